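"""MCMC sampler: convergence diagnostics, point estimates, posterior oracle."""

import numpy as np
import pytest
from scipy.special import expit

import iremirt as ir
from iremirt.sampler import Model, PosteriorDraws


def _draws_from_arrays(chains_by_param, config=None):
    """Wrap raw arrays as PosteriorDraws for diagnostic unit tests."""
    cfg = config or ir.SamplerConfig(iterations=20, burn_in=10, chains=2, seed=0)
    any_arr = next(iter(chains_by_param.values()))
    return PosteriorDraws(
        model=Model.TWO_PL,
        params=chains_by_param,
        n_respondents=1,
        n_items=1,
        config=cfg,
        priors=ir.PriorSpec(),
        irf_config=ir.IRFConfig(),
    )


class TestRhat:
    def test_identical_stationary_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10_000)
        d = _draws_from_arrays({"theta": np.stack([x, x])})
        report = ir.rhat(d)
        assert report.rhat["theta"] == pytest.approx(1.0, abs=0.01)

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        d = _draws_from_arrays({"theta": np.stack([x, x + 10.0])})
        report = ir.rhat(d)
        assert report.rhat["theta"] > 1.2
        assert report.flagged["theta"]

    def test_constant_chains_degenerate(self):
        d = _draws_from_arrays({"theta": np.ones((2, 100))})
        report = ir.rhat(d)
        assert report.rhat["theta"] == 1.0
        assert report.degenerate["theta"]

    def test_single_chain_rejected(self):
        d = _draws_from_arrays(
            {"theta": np.zeros((1, 100))},
            config=ir.SamplerConfig(iterations=20, burn_in=10, chains=1, seed=0),
        )
        with pytest.raises(ir.InvalidParameterError):
            ir.rhat(d)

    def test_agrees_with_arviz(self):
        import warnings

        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 800)) + rng.standard_normal((3, 1))[..., :1] * 0.2
        d = _draws_from_arrays(
            {"theta": x},
            config=ir.SamplerConfig(iterations=20, burn_in=10, chains=3, seed=0),
        )
        mine = float(ir.rhat(d).rhat["theta"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import arviz as az

            ref = float(az.rhat(az.convert_to_dataset(x[:, :, None]))["x"].values.squeeze())
        # rank-normalised arviz R-hat vs split Brooks-Gelman form: same regime
        assert mine == pytest.approx(ref, abs=0.05)


class TestPointEstimates:
    def test_mean_of_draws(self):
        d = _draws_from_arrays(
            {
                "theta": np.array([[1.0, 2.0], [3.0, 2.0]])[:, :, None],
                "b": np.array([[0.0, 0.0], [0.0, 0.0]])[:, :, None],
                "a": np.array([[1.0, 1.0], [1.0, 1.0]])[:, :, None],
            }
        )
        resp, items = ir.point_estimates(d)
        assert resp.theta[0] == pytest.approx(2.0)  # pooled mean of {1,2,3,2}
        assert resp.eps[0] == 1.0  # classic models carry eps = 1

    def test_pooled_equals_mean_of_chain_means(self):
        rng = np.random.default_rng(3)
        arr = rng.standard_normal((3, 50, 2))
        d = _draws_from_arrays(
            {"theta": arr, "b": np.ones((3, 50, 1)), "a": np.ones((3, 50, 1))},
            config=ir.SamplerConfig(iterations=20, burn_in=10, chains=3, seed=0),
        )
        resp, _ = ir.point_estimates(d)
        np.testing.assert_allclose(resp.theta, arr.mean(axis=(0, 1)))


class TestInitialValues:
    def test_reproducible_and_distinct_per_chain(self):
        a = ir.initial_values(Model.IREM, 10, 5, chain_index=0, seed=42)
        b = ir.initial_values(Model.IREM, 10, 5, chain_index=0, seed=42)
        c = ir.initial_values(Model.IREM, 10, 5, chain_index=1, seed=42)
        np.testing.assert_array_equal(a["theta"], b["theta"])
        assert not np.array_equal(a["theta"], c["theta"])

    def test_scales_positive_through_log_parameterisation(self):
        for model in Model:
            state = ir.initial_values(model, 10, 5, 0, 1)
            for key in ("log_eps", "log_sigma", "log_a", "log_sigma_a"):
                if key in state:
                    assert np.all(np.isfinite(state[key]))


class TestFit:
    def test_smoke_tiny_matrix(self):
        rng = np.random.default_rng(4)
        Y = rng.integers(0, 2, size=(20, 5))
        Y[0] = 1  # degenerate all-1 row must warn, not fail
        cfg = ir.SamplerConfig(iterations=300, burn_in=150, chains=2, seed=4)
        for model in Model:
            draws = ir.fit(Y, model, config=cfg)
            report = ir.rhat(draws)
            assert np.all(np.isfinite(np.concatenate(
                [np.atleast_1d(v).ravel() for v in report.rhat.values()]
            )))

    def test_positive_scale_draws(self, small_irem_fit):
        assert np.all(small_irem_fit.pooled("eps") > 0)
        assert np.all(small_irem_fit.pooled("sigma") > 0)

    def test_seeded_fit_bit_reproducible(self):
        rng = np.random.default_rng(5)
        Y = rng.integers(0, 2, size=(15, 4))
        cfg = ir.SamplerConfig(iterations=200, burn_in=100, chains=2, seed=5)
        d1 = ir.fit(Y, Model.TWO_PL, config=cfg)
        d2 = ir.fit(Y, Model.TWO_PL, config=cfg)
        for name in d1.params:
            np.testing.assert_array_equal(d1.params[name], d2.params[name])

    def test_theta_recovery_on_irem_data(self):
        """EAP abilities track the truth on a moderately sized IREM dataset."""
        rng = np.random.default_rng(6)
        resp = ir.draw_respondents(150, ir.EpsMode.LOGNORMAL, rng)
        items = ir.draw_items(25, rng)
        Y = ir.simulate_matrix(resp, items, ir.GeneratorKind.IREM, seed=rng)
        cfg = ir.SamplerConfig(iterations=2000, burn_in=1000, chains=2, seed=6)
        draws = ir.fit(Y, Model.IREM, config=cfg)
        est, _ = ir.point_estimates(draws)
        assert np.corrcoef(est.theta, resp.theta)[0, 1] > 0.8

    def test_irem_with_clamped_eps_reproduces_2pl(self):
        """Fixing every within-person SD collapses the IREM onto a 2PL.

        Data come from the constant-eps process (slopes 1/sqrt(1+sigma^2)),
        which both the clamped IREM and the free 2PL cover, so the two fits
        must order abilities identically up to Monte-Carlo noise.
        """
        rng = np.random.default_rng(8)
        resp = ir.draw_respondents(150, ir.EpsMode.CONSTANT_ONE, rng)
        items = ir.draw_items(20, rng)
        Y = ir.simulate_matrix(resp, items, ir.GeneratorKind.IREM, seed=rng)
        cfg = ir.SamplerConfig(iterations=4000, burn_in=2000, chains=2, seed=8)
        d_irem = ir.fit(Y, Model.IREM, config=cfg, fix_eps=1.0)
        d_2pl = ir.fit(Y, Model.TWO_PL, config=cfg)
        t_irem, _ = ir.point_estimates(d_irem)
        t_2pl, _ = ir.point_estimates(d_2pl)
        assert np.corrcoef(t_irem.theta, t_2pl.theta)[0, 1] > 0.99


class TestPosteriorOracle:
    def test_marginal_matches_dense_grid(self):
        """One-cell toy: MCMC theta marginal vs numerical posterior.

        Pinning b (through the fixed difficulty hyperprior), sigma (tiny
        log-sigma prior scale) and eps leaves a single free parameter with
        posterior proportional to N(theta; 0,1) * logistic(D*theta/sqrt(2)).
        """
        priors = ir.PriorSpec(log_sigma_scale=1e-9, b_hyper_fixed=(0.0, 1e-9))
        cfg = ir.SamplerConfig(iterations=12_000, burn_in=2_000, chains=2, seed=9)
        draws = ir.fit(np.array([[1]]), Model.IREM, priors=priors, config=cfg, fix_eps=1.0)
        theta = draws.pooled("theta").ravel()

        grid = np.linspace(-8, 8, 40_001)
        slope = 1.0 / np.sqrt(2.0)
        dens = np.exp(-0.5 * grid**2) * expit(1.7 * slope * grid)
        dens /= np.trapezoid(dens, grid)
        mean_oracle = np.trapezoid(grid * dens, grid)
        sd_oracle = np.sqrt(np.trapezoid((grid - mean_oracle) ** 2 * dens, grid))

        # conservative Monte-Carlo SE using an effective sample size >= n/20
        n_eff = theta.size / 20.0
        se_mean = sd_oracle / np.sqrt(n_eff)
        assert theta.mean() == pytest.approx(mean_oracle, abs=3 * se_mean)
        assert theta.std() == pytest.approx(sd_oracle, abs=3 * sd_oracle / np.sqrt(n_eff))
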