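"""Bayesian estimation of 1PL, 2PL and IREM by Metropolis-within-Gibbs MCMC.

Priors
------
theta_i ~ N(0, 1)                       (ability; anchors the scale)
ln a_j  ~ N(0, sigma_a^2)               (classic slopes)
b_j     ~ N(mu_b, sigma_b^2)            (difficulties)
mu_b    ~ Cauchy(0, 5)
sigma_b ~ half-Cauchy(0, 5)
sigma_a ~ half-Cauchy(0, 5)
ln sigma_j ~ N(0, 1)                    (IREM item threshold SD)
ln eps_i   ~ N(0, sigma_eps^2)          (IREM within-person SD)
sigma_eps  ~ half-Cauchy(0, 5)

The location/scale hyperparameters mu_b, sigma_b, sigma_a, sigma_eps are
shared across items/respondents; per-unit hyperpriors would have a single
datum each and be unidentifiable.  The learned sigma_eps gives the
within-person SDs adaptive shrinkage — essential for the S_eps-hat
model-selection statistic (see PriorSpec); a fixed ln eps_i ~ N(0, 1) prior
is available through ``PriorSpec(eps_hierarchical=False)``.

Sampler design
--------------
Component-wise adaptive random-walk Metropolis.  All theta_i (and, for the
IREM, all ln eps_i) are conditionally independent given the item parameters,
and all b_j / ln sigma_j / ln a_j given the respondent parameters, so each
block is proposed and accepted elementwise in a single vectorised sweep.
Per-component proposal SDs adapt by Robbins-Monro toward a 0.44 acceptance
rate during burn-in and are frozen afterwards, so the retained chains are
Markovian.  Scale parameters are updated on the log scale and therefore never
leave (0, inf).

Identifiability note: the likelihood depends on eps_i and sigma_j only
through eps_i^2 + sigma_j^2, which is invariant to transferring a common
constant between all within-person and all item variances.  The lognormal
priors resolve the split, so eps-hat is interpretable in relative, not
absolute, terms — the quantity the S_eps-hat statistic needs.

The paper-scale protocol is 10,000 iterations with 5,000 burn-in over three
chains; a reduced 4,000 / 2,000 two-chain profile
(:meth:`SamplerConfig.reduced`) is used for test-scale recovery runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .irf import (
    DEFAULT_D,
    IRFConfig,
    InvalidParameterError,
    ItemParams,
    RespondentParams,
    ResponseMatrix,
)

__all__ = [
    "Model",
    "PriorSpec",
    "SamplerConfig",
    "PosteriorDraws",
    "ConvergenceReport",
    "fit",
    "rhat",
    "point_estimates",
    "initial_values",
    "pointwise_loglik",
]

logger = logging.getLogger("iremirt")


class Model(str, Enum):
    ONE_PL = "1PL"
    TWO_PL = "2PL"
    IREM = "IREM"


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the prior; defaults follow the estimation recipe.

    By default the within-person scale prior is hierarchical:
    ln eps_i ~ N(0, sigma_eps^2) with sigma_eps ~ half-Cauchy(0, 5), exactly
    parallel to the slope prior ln a_j ~ N(0, sigma_a^2).  The adaptive
    shrinkage is what makes S_eps-hat usable for model selection: on
    homogeneous data sigma_eps collapses and every eps-hat is pulled to a
    common value, while genuinely heterogeneous data keep sigma_eps (and the
    eps-hat spread) away from zero.  Set ``eps_hierarchical=False`` for a
    fixed ln eps_i ~ N(log_eps_mean, log_eps_scale^2) prior, under which the
    weakly-informed per-respondent posteriors retain a large spread even on
    homogeneous data.
    """

    theta_scale: float = 1.0
    log_eps_mean: float = 0.0
    log_eps_scale: float = 1.0
    eps_hierarchical: bool = True
    sigma_eps_cauchy_scale: float = 5.0
    log_sigma_mean: float = 0.0
    log_sigma_scale: float = 1.0
    mu_b_cauchy_scale: float = 5.0
    sigma_b_cauchy_scale: float = 5.0
    sigma_a_cauchy_scale: float = 5.0
    #: optional (mu_b, sigma_b) override that fixes the difficulty prior and
    #: disables the hyperparameter updates; used for prior overrides and for
    #: reducing the posterior to low-dimensional special cases
    b_hyper_fixed: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        for name in (
            "theta_scale",
            "log_eps_scale",
            "log_sigma_scale",
            "mu_b_cauchy_scale",
            "sigma_b_cauchy_scale",
            "sigma_a_cauchy_scale",
            "sigma_eps_cauchy_scale",
        ):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings.

    ``iterations``/``burn_in``/``chains`` default to the production protocol
    (10,000 / 5,000 / 3); :meth:`reduced` gives the scaled-down recovery-run
    profile.  ``target_accept`` is the per-scalar-component Robbins-Monro
    target; ``rhat_threshold`` the screening level for the convergence report.
    """

    iterations: int = 10_000
    burn_in: int = 5_000
    chains: int = 3
    seed: int = 0
    target_accept: float = 0.44
    adapt: bool = True
    rhat_threshold: float = 1.2
    thin: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise InvalidParameterError("require 0 <= burn_in < iterations")
        if self.chains < 1:
            raise InvalidParameterError("chains must be >= 1")
        if not 0 < self.target_accept < 1:
            raise InvalidParameterError("target_accept in (0, 1)")
        if self.thin < 1:
            raise InvalidParameterError("thin must be >= 1")

    @classmethod
    def reduced(cls, seed: int = 0, chains: int = 2) -> "SamplerConfig":
        """Scaled-down profile for recovery runs: 4,000 iterations, 2,000 burn-in."""
        return cls(iterations=4_000, burn_in=2_000, chains=chains, seed=seed)


@dataclass
class ConvergenceReport:
    """Split-chain potential scale reduction factors and exceedance flags."""

    rhat: Dict[str, np.ndarray]
    threshold: float
    degenerate: Dict[str, np.ndarray]

    @property
    def max_rhat(self) -> float:
        return max(float(np.max(v)) for v in self.rhat.values())

    @property
    def flagged(self) -> Dict[str, np.ndarray]:
        """Boolean mask per parameter marking components with R-hat above threshold."""
        return {k: v > self.threshold for k, v in self.rhat.items()}

    @property
    def converged(self) -> bool:
        return self.max_rhat < self.threshold


@dataclass
class PosteriorDraws:
    """Per-chain post-burn-in draws for every sampled parameter.

    ``params`` maps a parameter name to an array of shape (chains, draws) for
    scalars or (chains, draws, dim) for vectors.  ``eps``/``sigma``/``a``
    draws are stored on the positive scale.
    """

    model: Model
    params: Dict[str, np.ndarray]
    n_respondents: int
    n_items: int
    config: SamplerConfig
    priors: PriorSpec
    irf_config: IRFConfig
    accept_rates: Dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        """Post-burn-in draws per chain."""
        return next(iter(self.params.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains: shape (chains * draws, ...)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])


# ---------------------------------------------------------------------------
# Initial values
# ---------------------------------------------------------------------------

#: inflation factor applied to prior scales so chains start over-dispersed
_OVERDISPERSION = 2.0

#: hard truncation of every log-scale parameter (scales in [e^-30, e^30]);
#: unreachable for realistic posteriors, prevents float overflow in the
#: heavy-tailed degenerate-data regime (tiny matrices, inconsistent rows)
_LOG_SCALE_BOUND = 30.0


def initial_values(
    model: Model,
    N: int,
    K: int,
    chain_index: int = 0,
    seed: int = 0,
    priors: PriorSpec = PriorSpec(),
) -> Dict[str, np.ndarray]:
    """Over-dispersed random starting state, distinct per chain, reproducible.

    Draws come from the priors with scales inflated on the unconstrained
    scale; scale parameters are initialised through their logs and are
    therefore always positive.  Heavy-tailed hyperparameter priors are
    initialised from moderate normals rather than raw Cauchy draws to avoid
    absurd starting points.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(chain_index)]))
    state: Dict[str, np.ndarray] = {
        "theta": rng.standard_normal(N) * priors.theta_scale * _OVERDISPERSION,
        "b": rng.standard_normal(K) * _OVERDISPERSION,
        "mu_b": np.array(rng.standard_normal() * _OVERDISPERSION),
        "log_sigma_b": np.array(rng.standard_normal() * 0.5),
    }
    if model is Model.IREM:
        state["log_eps"] = (
            priors.log_eps_mean
            + rng.standard_normal(N) * priors.log_eps_scale * _OVERDISPERSION
        )
        state["log_sigma"] = (
            priors.log_sigma_mean
            + rng.standard_normal(K) * priors.log_sigma_scale * _OVERDISPERSION
        )
        if priors.eps_hierarchical:
            state["log_sigma_eps"] = np.array(rng.standard_normal() * 0.5)
    else:
        dim = K if model is Model.TWO_PL else 1
        state["log_a"] = rng.standard_normal(dim) * 0.75
        state["log_sigma_a"] = np.array(rng.standard_normal() * 0.5)
    return state


# ---------------------------------------------------------------------------
# Chain internals
# ---------------------------------------------------------------------------


try:  # fused kernels; pure-NumPy fallback below keeps the package importable
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(**kwargs):
        def deco(f):
            return f

        return deco


@_njit(cache=False, fastmath=True)
def _ll_irem_kernel(sign_neg, theta, b, eps, sigma, D):  # pragma: no cover
    N, K = sign_neg.shape
    out = np.empty((N, K))
    for i in range(N):
        e2 = eps[i] * eps[i]
        th = theta[i]
        for j in range(K):
            s = D * (th - b[j]) / np.sqrt(e2 + sigma[j] * sigma[j])
            x = sign_neg[i, j] * s
            if x > 0.0:
                out[i, j] = -(x + np.log1p(np.exp(-x)))
            else:
                out[i, j] = -np.log1p(np.exp(x))
    return out


@_njit(cache=False, fastmath=True)
def _ll_classic_kernel(sign_neg, theta, b, a, D):  # pragma: no cover
    N, K = sign_neg.shape
    out = np.empty((N, K))
    for i in range(N):
        th = theta[i]
        for j in range(K):
            x = sign_neg[i, j] * D * a[j] * (th - b[j])
            if x > 0.0:
                out[i, j] = -(x + np.log1p(np.exp(-x)))
            else:
                out[i, j] = -np.log1p(np.exp(x))
    return out


def _loglik_matrix(
    sign_neg: np.ndarray,
    theta: np.ndarray,
    b: np.ndarray,
    model: Model,
    D: float,
    eps: Optional[np.ndarray] = None,
    sigma: Optional[np.ndarray] = None,
    a: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pointwise Bernoulli log-likelihood from logits, numerically stable.

    ``sign_neg`` is the precomputed (1 - 2 y) matrix; the identity
    y ln p + (1-y) ln(1-p) = -ln(1 + exp((1-2y) s)) avoids forming p.
    """
    if _HAVE_NUMBA:
        if model is Model.IREM:
            return _ll_irem_kernel(sign_neg, theta, b, eps, sigma, float(D))
        return _ll_classic_kernel(sign_neg, theta, b, a, float(D))
    diff = theta[:, None] - b[None, :]
    if model is Model.IREM:
        s = D * diff / np.sqrt(eps[:, None] ** 2 + sigma[None, :] ** 2)
    else:
        s = D * a[None, :] * diff
    return -np.logaddexp(0.0, sign_neg * s)


def _cauchy_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return -np.log1p((x / scale) ** 2)  # up to a constant


class _Adapter:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, size: int, target: float):
        self.log_step = np.full(size, np.log(0.5))
        self.target = target

    def step(self) -> np.ndarray:
        return np.exp(self.log_step)

    def update(self, alpha: np.ndarray, t: int) -> None:
        gamma = (t + 1.0) ** -0.6
        self.log_step += gamma * (alpha - self.target)


def _run_chain(
    y: np.ndarray,
    model: Model,
    priors: PriorSpec,
    config: SamplerConfig,
    irf_config: IRFConfig,
    chain_index: int,
    fix_eps: Optional[float],
) -> Tuple[Dict[str, np.ndarray], Dict[str, float]]:
    N, K = y.shape
    D = irf_config.D
    sign_neg = (1.0 - 2.0 * y).astype(float)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(chain_index), 17])
    )
    state = initial_values(model, N, K, chain_index, config.seed, priors)
    irem = model is Model.IREM
    if irem and fix_eps is not None:
        state["log_eps"] = np.full(N, np.log(fix_eps))
    fixed_b_hyper = priors.b_hyper_fixed is not None
    if fixed_b_hyper:
        state["mu_b"] = np.array(float(priors.b_hyper_fixed[0]))
        state["log_sigma_b"] = np.array(np.log(priors.b_hyper_fixed[1]))

    def current_ll() -> np.ndarray:
        if irem:
            return _loglik_matrix(
                sign_neg, state["theta"], state["b"], model, D,
                eps=np.exp(state["log_eps"]), sigma=np.exp(state["log_sigma"]),
            )
        a = np.exp(state["log_a"])
        a_full = np.broadcast_to(a, (K,)) if a.size == K else np.full(K, a[0])
        return _loglik_matrix(sign_neg, state["theta"], state["b"], model, D, a=a_full)

    ll = current_ll()

    adapters = {"theta": _Adapter(N, config.target_accept),
                "b": _Adapter(K, config.target_accept),
                "mu_b": _Adapter(1, config.target_accept),
                "log_sigma_b": _Adapter(1, config.target_accept)}
    hier_eps = irem and priors.eps_hierarchical and fix_eps is None
    if irem:
        if fix_eps is None:
            adapters["log_eps"] = _Adapter(N, config.target_accept)
            if hier_eps:
                adapters["log_sigma_eps"] = _Adapter(1, config.target_accept)
                adapters["rescale_eps"] = _Adapter(1, config.target_accept)
        adapters["log_sigma"] = _Adapter(K, config.target_accept)
    else:
        adapters["log_a"] = _Adapter(state["log_a"].size, config.target_accept)
        adapters["log_sigma_a"] = _Adapter(1, config.target_accept)

    n_keep = (config.iterations - config.burn_in) // config.thin
    store: Dict[str, np.ndarray] = {
        "theta": np.empty((n_keep, N)),
        "b": np.empty((n_keep, K)),
        "mu_b": np.empty(n_keep),
        "sigma_b": np.empty(n_keep),
    }
    if irem:
        store["eps"] = np.empty((n_keep, N))
        store["sigma"] = np.empty((n_keep, K))
        if hier_eps:
            store["sigma_eps"] = np.empty(n_keep)
    else:
        store["a"] = np.empty((n_keep, state["log_a"].size))
        store["sigma_a"] = np.empty(n_keep)

    acc_counts: Dict[str, float] = {k: 0.0 for k in adapters}
    acc_iters = 0

    def _row_update(
        name: str, t: int, prior_mean: float, prior_sd: float, bounded: bool = False
    ) -> None:
        """Vectorised elementwise MH over the N conditionally independent rows."""
        nonlocal ll
        cur = state[name]
        step = adapters[name].step()
        prop = cur + step * rng.standard_normal(N)
        st = dict(state)
        st[name] = prop
        if irem:
            ll_new = _loglik_matrix(
                sign_neg, st["theta"], st["b"], model, D,
                eps=np.exp(st["log_eps"]), sigma=np.exp(st["log_sigma"]),
            )
        else:
            a = np.exp(st["log_a"])
            a_full = np.broadcast_to(a, (K,)) if a.size == K else np.full(K, a[0])
            ll_new = _loglik_matrix(sign_neg, st["theta"], st["b"], model, D, a=a_full)
        d = (ll_new - ll).sum(axis=1)
        d += 0.5 * ((cur - prior_mean) ** 2 - (prop - prior_mean) ** 2) / prior_sd**2
        if bounded:
            d = np.where(np.abs(prop) > _LOG_SCALE_BOUND, -np.inf, d)
        alpha = np.exp(np.minimum(0.0, d))
        acc = rng.random(N) < alpha
        cur[acc] = prop[acc]
        ll[acc] = ll_new[acc]
        if t < config.burn_in and config.adapt:
            adapters[name].update(alpha, t)
        else:
            acc_counts[name] += acc.mean()

    def _col_update(
        name: str, t: int, prior_mean, prior_sd: float, bounded: bool = False
    ) -> None:
        """Vectorised elementwise MH over the K conditionally independent columns."""
        nonlocal ll
        cur = state[name]
        size = cur.size
        step = adapters[name].step()
        prop = cur + step * rng.standard_normal(size)
        st = dict(state)
        st[name] = prop
        if irem:
            ll_new = _loglik_matrix(
                sign_neg, st["theta"], st["b"], model, D,
                eps=np.exp(st["log_eps"]), sigma=np.exp(st["log_sigma"]),
            )
        else:
            a = np.exp(st["log_a"])
            a_full = np.broadcast_to(a, (K,)) if a.size == K else np.full(K, a[0])
            ll_new = _loglik_matrix(sign_neg, st["theta"], st["b"], model, D, a=a_full)
        if size == 1:  # shared 1PL slope: one global accept/reject
            d = np.array([(ll_new - ll).sum()])
        else:
            d = (ll_new - ll).sum(axis=0)
        d += 0.5 * ((cur - prior_mean) ** 2 - (prop - prior_mean) ** 2) / prior_sd**2
        if bounded:
            d = np.where(np.abs(prop) > _LOG_SCALE_BOUND, -np.inf, d)
        alpha = np.exp(np.minimum(0.0, d))
        acc = rng.random(size) < alpha
        cur[acc] = prop[acc]
        if size == 1:
            if acc[0]:
                ll = ll_new
        else:
            ll[:, acc] = ll_new[:, acc]
        if t < config.burn_in and config.adapt:
            adapters[name].update(alpha, t)
        else:
            acc_counts[name] += acc.mean()

    def _scalar_update(name: str, t: int, logpost) -> None:
        cur = float(state[name])
        step = adapters[name].step()[0]
        prop = cur + step * rng.standard_normal()
        d = logpost(prop) - logpost(cur)
        alpha = float(np.exp(min(0.0, d)))
        accepted = rng.random() < alpha
        if accepted:
            state[name] = np.array(prop)
        if t < config.burn_in and config.adapt:
            adapters[name].update(np.array([alpha]), t)
        else:
            acc_counts[name] += float(accepted)

    def _mu_b_logpost(mu: float) -> float:
        sb = float(np.exp(state["log_sigma_b"]))
        return (
            -0.5 * float(np.sum((state["b"] - mu) ** 2)) / sb**2
            + float(_cauchy_logpdf(np.array(mu), priors.mu_b_cauchy_scale))
        )

    def _log_sigma_b_logpost(ls: float) -> float:
        if abs(ls) > _LOG_SCALE_BOUND:
            return -np.inf
        sb = np.exp(ls)
        ssq = float(np.sum((state["b"] - float(state["mu_b"])) ** 2))
        # normal likelihood of b + half-Cauchy prior + log-scale Jacobian
        return (
            -K * ls
            - 0.5 * ssq / sb**2
            + float(_cauchy_logpdf(np.array(sb), priors.sigma_b_cauchy_scale))
            + ls
        )

    def _log_sigma_eps_logpost(ls: float) -> float:
        if abs(ls) > _LOG_SCALE_BOUND:
            return -np.inf
        se = np.exp(ls)
        le = state["log_eps"] - priors.log_eps_mean
        ssq = float(np.sum(le**2))
        return (
            -N * ls
            - 0.5 * ssq / se**2
            + float(_cauchy_logpdf(np.array(se), priors.sigma_eps_cauchy_scale))
            + ls
        )

    def _rescale_eps_update(t: int) -> None:
        """Interweaved non-centred move along the hierarchical funnel.

        Holding the standardised residuals z_i = (ln eps_i - mu) / sigma_eps
        fixed, propose a new sigma_eps; all ln eps_i rescale with it, so one
        accept/reject moves the whole hierarchy.  In the non-centred
        parameterisation the z_i prior does not involve sigma_eps, leaving
        the likelihood, the half-Cauchy prior and the log-scale Jacobian.
        """
        nonlocal ll
        ls = float(state["log_sigma_eps"])
        step = adapters["rescale_eps"].step()[0]
        ls_new = ls + step * rng.standard_normal()
        z = (state["log_eps"] - priors.log_eps_mean) / np.exp(ls)
        log_eps_new = priors.log_eps_mean + np.exp(ls_new) * z
        if (
            abs(ls_new) > _LOG_SCALE_BOUND
            or np.max(np.abs(log_eps_new)) > _LOG_SCALE_BOUND
        ):
            if t < config.burn_in and config.adapt:
                adapters["rescale_eps"].update(np.array([0.0]), t)
            return
        ll_new = _loglik_matrix(
            sign_neg, state["theta"], state["b"], model, D,
            eps=np.exp(log_eps_new), sigma=np.exp(state["log_sigma"]),
        )
        d = (ll_new - ll).sum()
        d += float(
            _cauchy_logpdf(np.exp(np.array(ls_new)), priors.sigma_eps_cauchy_scale)
            - _cauchy_logpdf(np.exp(np.array(ls)), priors.sigma_eps_cauchy_scale)
        )
        d += ls_new - ls  # Jacobian of sigma_eps = exp(log sigma_eps)
        alpha = float(np.exp(min(0.0, d)))
        accepted = rng.random() < alpha
        if accepted:
            state["log_sigma_eps"] = np.array(ls_new)
            state["log_eps"] = log_eps_new
            ll = ll_new
        if t < config.burn_in and config.adapt:
            adapters["rescale_eps"].update(np.array([alpha]), t)
        else:
            acc_counts["rescale_eps"] += float(accepted)

    def _log_sigma_a_logpost(ls: float) -> float:
        if abs(ls) > _LOG_SCALE_BOUND:
            return -np.inf
        sa = np.exp(ls)
        la = state["log_a"]
        ssq = float(np.sum(la**2))
        return (
            -la.size * ls
            - 0.5 * ssq / sa**2
            + float(_cauchy_logpdf(np.array(sa), priors.sigma_a_cauchy_scale))
            + ls
        )

    keep_idx = 0
    for t in range(config.iterations):
        _row_update("theta", t, 0.0, priors.theta_scale)
        if irem and fix_eps is None:
            eps_prior_sd = (
                float(np.exp(state["log_sigma_eps"])) if hier_eps else priors.log_eps_scale
            )
            _row_update("log_eps", t, priors.log_eps_mean, eps_prior_sd, bounded=True)
            if hier_eps:
                _scalar_update("log_sigma_eps", t, _log_sigma_eps_logpost)
                _rescale_eps_update(t)
        sb = float(np.exp(state["log_sigma_b"]))
        _col_update("b", t, float(state["mu_b"]), sb)
        if irem:
            _col_update(
                "log_sigma", t, priors.log_sigma_mean, priors.log_sigma_scale,
                bounded=True,
            )
        else:
            _col_update(
                "log_a", t, 0.0, float(np.exp(state["log_sigma_a"])), bounded=True
            )
            _scalar_update("log_sigma_a", t, _log_sigma_a_logpost)
        if not fixed_b_hyper:
            _scalar_update("mu_b", t, _mu_b_logpost)
            _scalar_update("log_sigma_b", t, _log_sigma_b_logpost)

        if t >= config.burn_in:
            acc_iters += 1
            if (t - config.burn_in) % config.thin == 0 and keep_idx < n_keep:
                store["theta"][keep_idx] = state["theta"]
                store["b"][keep_idx] = state["b"]
                store["mu_b"][keep_idx] = float(state["mu_b"])
                store["sigma_b"][keep_idx] = float(np.exp(state["log_sigma_b"]))
                if irem:
                    store["eps"][keep_idx] = np.exp(state["log_eps"])
                    store["sigma"][keep_idx] = np.exp(state["log_sigma"])
                    if hier_eps:
                        store["sigma_eps"][keep_idx] = float(
                            np.exp(state["log_sigma_eps"])
                        )
                else:
                    store["a"][keep_idx] = np.exp(state["log_a"])
                    store["sigma_a"][keep_idx] = float(np.exp(state["log_sigma_a"]))
                keep_idx += 1

    rates = {k: v / max(acc_iters, 1) for k, v in acc_counts.items()}
    return store, rates


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def fit(
    Y: Union[ResponseMatrix, np.ndarray],
    model: Union[Model, str] = Model.IREM,
    priors: PriorSpec = PriorSpec(),
    config: SamplerConfig = SamplerConfig(),
    irf_config: IRFConfig = IRFConfig(),
    fix_eps: Optional[float] = None,
) -> PosteriorDraws:
    """Run multi-chain MCMC and return post-burn-in draws.

    Parameters
    ----------
    Y : ResponseMatrix or array
        N x K binary response matrix.
    model : Model
        ONE_PL, TWO_PL or IREM.
    fix_eps : float, optional
        Clamp every within-person SD to this value (IREM only); with
        ``fix_eps=1`` the IREM collapses to a 2PL parameterised through the
        item threshold SDs.

    Non-convergence is reported through :func:`rhat`, never raised; degenerate
    all-0/all-1 rows or columns trigger a warning and proceed (the priors
    regularise them).
    """
    model = Model(model)
    y = Y.scores if isinstance(Y, ResponseMatrix) else np.atleast_2d(np.asarray(Y))
    if not np.all(np.isin(y, (0, 1))):
        raise InvalidParameterError("Y must be binary")
    y = y.astype(float)
    n_zero = int(np.sum(~y.any(axis=1)) + np.sum(y.all(axis=1)))
    k_zero = int(np.sum(~y.any(axis=0)) + np.sum(y.all(axis=0)))
    if n_zero or k_zero:
        logger.warning(
            "fit: %d all-0/all-1 row(s) and %d such column(s); "
            "proceeding (priors regularise extreme patterns)", n_zero, k_zero,
        )
    stores: List[Dict[str, np.ndarray]] = []
    rate_sum: Dict[str, float] = {}
    for c in range(config.chains):
        store, rates = _run_chain(y, model, priors, config, irf_config, c, fix_eps)
        stores.append(store)
        for k, v in rates.items():
            rate_sum[k] = rate_sum.get(k, 0.0) + v
        logger.info(
            "chain %d/%d done; post-burn-in acceptance: %s",
            c + 1, config.chains,
            {k: round(v, 3) for k, v in rates.items()},
        )
    params = {
        name: np.stack([s[name] for s in stores], axis=0) for name in stores[0]
    }
    return PosteriorDraws(
        model=model,
        params=params,
        n_respondents=y.shape[0],
        n_items=y.shape[1],
        config=config,
        priors=priors,
        irf_config=irf_config,
        accept_rates={k: v / config.chains for k, v in rate_sum.items()},
    )


def rhat(draws: PosteriorDraws) -> ConvergenceReport:
    """Split-chain potential scale reduction factor for every parameter.

    Each chain is split in half, giving 2C sequences; R-hat is
    sqrt(var_plus / W) with var_plus = (n-1)/n W + B/n (the Brooks-Gelman
    corrected form).  Chains with zero within-variance are reported as 1.0
    with a degenerate flag.
    """
    if draws.n_chains < 2:
        raise InvalidParameterError("rhat requires at least 2 chains")
    if draws.n_draws < 10:
        raise InvalidParameterError("rhat requires at least 10 draws per chain")
    out: Dict[str, np.ndarray] = {}
    degen: Dict[str, np.ndarray] = {}
    for name, arr in draws.params.items():
        if arr.ndim == 2:
            arr = arr[:, :, None]
        c, s, dim = arr.shape
        half = s // 2
        split = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
        m, n = split.shape[0], split.shape[1]
        chain_means = split.mean(axis=1)                    # (m, dim)
        chain_vars = split.var(axis=1, ddof=1)              # (m, dim)
        W = chain_vars.mean(axis=0)
        B_over_n = chain_means.var(axis=0, ddof=1)
        var_plus = (n - 1) / n * W + B_over_n
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.sqrt(var_plus / W)
        is_degen = W == 0
        r = np.where(is_degen, 1.0, r)
        out[name] = r.squeeze() if draws.params[name].ndim == 2 else r
        degen[name] = is_degen.squeeze() if draws.params[name].ndim == 2 else is_degen
    return ConvergenceReport(rhat=out, threshold=draws.config.rhat_threshold, degenerate=degen)


def point_estimates(
    draws: PosteriorDraws,
) -> Tuple[RespondentParams, ItemParams]:
    """Point estimates from pooled post-burn-in draws.

    Location parameters (theta, b) are EAP posterior means.  The
    positive-scale parameters (eps, sigma, a) are summarised by the
    posterior median: their marginals are lognormal-like, and for weakly
    informed respondents the posterior-mean eps-hat is dominated by the
    right tail, which would inflate the spread statistic S_eps-hat on
    homogeneous data.  Classic models report eps identically 1 and
    sigma = 1/a-hat.
    """
    if draws.n_draws == 0:
        raise InvalidParameterError("no draws to summarise")
    theta_hat = draws.pooled("theta").mean(axis=0)
    b_hat = draws.pooled("b").mean(axis=0)
    if draws.model is Model.IREM:
        eps_hat = np.median(draws.pooled("eps"), axis=0)
        sigma_hat = np.median(draws.pooled("sigma"), axis=0)
        resp = RespondentParams(theta=theta_hat, eps=eps_hat)
        items = ItemParams(b=b_hat, sigma=sigma_hat)
    else:
        a_hat = np.median(draws.pooled("a"), axis=0)
        if a_hat.size == 1:
            a_hat = np.full(b_hat.size, a_hat[0])
        resp = RespondentParams(theta=theta_hat, eps=np.ones(theta_hat.size))
        items = ItemParams(b=b_hat, a=a_hat)
    return resp, items


def pointwise_loglik(
    draws: PosteriorDraws,
    Y: Union[ResponseMatrix, np.ndarray],
    max_draws: int = 500,
) -> np.ndarray:
    """Draws x cells pointwise log-likelihood table for WAIC/LOO.

    Pooled post-burn-in draws are thinned evenly to at most ``max_draws``
    rows; columns run over the flattened N x K cells.
    """
    y = Y.scores if isinstance(Y, ResponseMatrix) else np.atleast_2d(np.asarray(Y))
    sign_neg = (1.0 - 2.0 * y).astype(float)
    D = draws.irf_config.D
    theta = draws.pooled("theta")
    b = draws.pooled("b")
    total = theta.shape[0]
    idx = np.unique(np.linspace(0, total - 1, min(max_draws, total)).astype(int))
    table = np.empty((idx.size, y.size))
    if draws.model is Model.IREM:
        eps = draws.pooled("eps")
        sigma = draws.pooled("sigma")
        for row, s in enumerate(idx):
            table[row] = _loglik_matrix(
                sign_neg, theta[s], b[s], draws.model, D, eps=eps[s], sigma=sigma[s]
            ).ravel()
    else:
        a = draws.pooled("a")
        for row, s in enumerate(idx):
            a_full = a[s] if a[s].size == y.shape[1] else np.full(y.shape[1], a[s][0])
            table[row] = _loglik_matrix(
                sign_neg, theta[s], b[s], draws.model, D, a=a_full
            ).ravel()
    return table
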