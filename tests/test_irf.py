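"""Item response functions: closed-form values, reductions and invariants."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import iremirt as ir

# error-function oracle, independent of the scipy.ndtr path used internally
def phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


class TestOgive:
    @pytest.mark.parametrize(
        "theta, b, a, expected",
        [
            (0.3, 0.3, 1.0, 0.5),                 # symmetry at theta = b
            (1.0, 0.0, 1.0, phi(1.0)),            # Phi(1) = 0.841345
            (2.0, 0.0, 2.5, phi(5.0)),
            (50.0, 0.0, 1.0, 1.0),                # CDF limit
        ],
    )
    def test_values(self, theta, b, a, expected):
        assert ir.ogive_prob(theta, b, a) == pytest.approx(expected, abs=1e-6)

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(ir.InvalidParameterError):
            ir.ogive_prob(0.0, 0.0, 0.0)
        with pytest.raises(ir.InvalidParameterError):
            ir.ogive_prob(0.0, 0.0, -1.0)


class TestIremOgive:
    @pytest.mark.parametrize(
        "theta, b, eps, sigma, expected",
        [
            (1.0, 1.0, 1.0, 1.0, 0.5),
            (1.0, 0.0, 0.0, 1.0, phi(1.0)),           # eps=0 reduces to 2PL/a=1
            (1.0, 0.0, 1.0, 1.0, phi(1 / math.sqrt(2))),  # 0.760250
        ],
    )
    def test_values(self, theta, b, eps, sigma, expected):
        assert ir.irem_prob_ogive(theta, b, eps, sigma) == pytest.approx(expected, abs=1e-6)

    def test_matches_classic_when_eps_zero(self):
        theta = np.linspace(-3, 3, 13)
        got = ir.irem_prob_ogive(theta, 0.4, 0.0, 0.5)
        want = ir.ogive_prob(theta, 0.4, 2.0)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_undefined_slope_rejected(self):
        with pytest.raises(ir.InvalidParameterError):
            ir.irem_prob_ogive(1.0, 0.0, 0.0, 0.0)


class TestLogistic:
    def test_symmetry_half(self):
        assert ir.irem_prob_logistic(0.7, 0.7, 2.0, 0.3) == pytest.approx(0.5)
        assert ir.classic_prob_logistic(0.7, 0.7, 1.3) == pytest.approx(0.5)

    def test_closed_form_values(self):
        want = 1.0 / (1.0 + math.exp(-1.7 / math.sqrt(2.0)))  # ~0.7689
        got = ir.irem_prob_logistic(1.0, 0.0, 1.0, 1.0)
        assert got == pytest.approx(want, abs=1e-12)
        assert abs(got - ir.irem_prob_ogive(1.0, 0.0, 1.0, 1.0)) < 0.01
        assert ir.classic_prob_logistic(1.0, 0.0, 2.0) == pytest.approx(
            1.0 / (1.0 + math.exp(-3.4)), abs=1e-12
        )

    def test_2pl_reduction_identity(self):
        """Constant eps makes the IREM a 2PL with slope 1/sqrt(eps^2+sigma^2)."""
        theta = np.linspace(-4, 4, 41)
        eps, sigma = 1.0, 1.0
        a = 1.0 / math.sqrt(eps**2 + sigma**2)
        np.testing.assert_allclose(
            ir.irem_prob_logistic(theta, 0.2, eps, sigma),
            ir.classic_prob_logistic(theta, 0.2, a),
            rtol=0, atol=1e-15,
        )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        theta=st.floats(-6, 6),
        b=st.floats(-6, 6),
        eps=st.floats(0.01, 5),
        sigma=st.floats(0.01, 5),
    )
    def test_bounds_monotonicity_and_link_gap(self, theta, b, eps, sigma):
        # keep the logit below float64 saturation so (0,1) strictness is meaningful
        assume(abs(1.7 * (theta - b)) / math.sqrt(eps**2 + sigma**2) < 30)
        p = float(ir.irem_prob_logistic(theta, b, eps, sigma))
        assert 0.0 < p < 1.0
        # monotone non-decreasing in theta, non-increasing in b
        assert float(ir.irem_prob_logistic(theta + 0.5, b, eps, sigma)) >= p
        assert float(ir.irem_prob_logistic(theta, b + 0.5, eps, sigma)) <= p
        # ogive/logistic gap below the 0.01 bound at D = 1.7
        assert abs(p - float(ir.irem_prob_ogive(theta, b, eps, sigma))) < 0.01


class TestHaleyGap:
    def test_zero_grid(self):
        assert ir.haley_max_gap(0.0, 0.0, 1.0) == 0.0

    def test_scaled_logistic_within_bound(self):
        assert ir.haley_max_gap(-10, 10, 1e-4) < 0.01

    def test_unscaled_logistic_violates_bound(self):
        assert ir.haley_max_gap(-10, 10, 1e-4, ir.IRFConfig(D=1.0)) > 0.01

    def test_precondition(self):
        with pytest.raises(ir.InvalidParameterError):
            ir.haley_max_gap(1.0, 0.0, 0.1)


class TestBernoulliLoglik:
    def test_single_cell(self):
        total, pointwise = ir.bernoulli_loglik(np.array([[1]]), np.array([[0.5]]))
        assert total == pytest.approx(math.log(0.5))
        assert pointwise.shape == (1, 1)

    def test_additivity_2x2(self):
        y = np.array([[1, 0], [0, 1]])
        p = np.array([[0.7, 0.2], [0.4, 0.9]])
        total, pointwise = ir.bernoulli_loglik(y, p)
        assert total == pytest.approx(pointwise.sum())

    def test_matches_brute_force_product(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=(3, 3))
        p = rng.uniform(0.05, 0.95, size=(3, 3))
        total, _ = ir.bernoulli_loglik(y, p)
        brute = math.log(float(np.prod(np.where(y == 1, p, 1 - p))))
        assert total == pytest.approx(brute, abs=1e-10)

    def test_contradicting_degenerate_cell_is_minus_inf(self):
        total, pointwise = ir.bernoulli_loglik(
            np.array([[1, 0]]), np.array([[0.0, 0.5]])
        )
        assert pointwise[0, 0] == -np.inf and total == -np.inf

    def test_shape_mismatch(self):
        with pytest.raises(ir.InvalidParameterError):
            ir.bernoulli_loglik(np.ones((2, 2), dtype=int), np.full((2, 3), 0.5))


class TestTypes:
    def test_respondent_params_validation(self):
        with pytest.raises(ir.InvalidParameterError):
            ir.RespondentParams(theta=[0.0, 1.0], eps=[1.0, 0.0])
        with pytest.raises(ir.InvalidParameterError):
            ir.RespondentParams(theta=[np.inf], eps=[1.0])

    def test_item_params_slope_consistency(self):
        items = ir.ItemParams(b=[0.0, 1.0], sigma=[0.5, 2.0])
        np.testing.assert_allclose(items.a * items.sigma, 1.0)
        items2 = ir.ItemParams(b=[0.0], a=[4.0])
        assert items2.sigma[0] == pytest.approx(0.25)

    def test_response_matrix_rejects_nonbinary(self):
        with pytest.raises(ir.InvalidParameterError):
            ir.ResponseMatrix(scores=np.array([[0, 2]]))

    def test_prob_matrix_broadcasting(self):
        resp = ir.RespondentParams(theta=[0.0, 1.0], eps=[1.0, 1.0])
        items = ir.ItemParams(b=[0.0, 0.0, 1.0], sigma=[1.0, 1.0, 1.0])
        P = ir.prob_matrix(resp, items, model="IREM")
        assert P.shape == (2, 3)
        assert P[0, 0] == pytest.approx(0.5)
        assert P[1, 2] == pytest.approx(0.5)
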