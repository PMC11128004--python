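# Methods

## The model

Classic dichotomous IRT assumes that two respondents with the same latent
ability θ have identical endorsement probabilities on every item. The
individual random effects model (IREM) implemented here drops that
homogeneity assumption: each respondent's momentary trait θ\* is normal with
mean θ and *within-person* variance ε², and each item's threshold η is
normal with mean b (difficulty) and threshold variance σ². The respondent
endorses the item when θ\* > η. Integrating both latent quantities out gives
the closed-form ogive response function

    P(Y = 1 | θ, b, ε, σ) = Φ( (θ − b) / √(ε² + σ²) ),

so the effective item slope for respondent i on item j is
1/√(ε_i² + σ_j²). With ε constant across respondents this is exactly the
two-parameter model with a = 1/σ; the IREM is a strict generalisation of the
2PL, and the 1PL is the further restriction to a single shared slope. For
computation the ogive is replaced by the logistic with scaling constant
D = 1.7, which tracks Φ to within 0.01 uniformly (`haley_max_gap` verifies
the bound numerically; `D` is configurable through `IRFConfig`).

Conditional independence holds given (θ_i, ε_i, b_j, σ_j), so the likelihood
is the product of Bernoulli cell probabilities (`bernoulli_loglik`).

**Identifiability.** The likelihood depends on the scale parameters only
through ε_i² + σ_j², which is invariant to moving a common constant between
all within-person and all item variances. The lognormal priors resolve the
split in estimation, but ε̂ should be read as a *relative* measure of
within-person spread, not an absolute variance — which is all the
model-selection statistic S_ε̂ requires.

## Priors and estimation

Priors: θ_i ~ N(0,1); b_j ~ N(μ_b, σ_b²) with μ_b ~ Cauchy(0,5) and
σ_b ~ half-Cauchy(0,5); classic slopes ln a_j ~ N(0, σ_a²) with
σ_a ~ half-Cauchy(0,5); IREM item scales ln σ_j ~ N(0,1); IREM within-person
scales ln ε_i ~ N(0, σ_ε²) with σ_ε ~ half-Cauchy(0,5). The hyperparameters
are shared across items/respondents (per-unit hyperpriors would have one
datum each and be unidentifiable). The 1PL shares a single ln a across
items under the same σ_a hyperprior.

The hierarchical ε prior is a deliberate design choice and matters for the
method. A single respondent's ε_i is weakly informed by K binary items, so
under a *fixed* ln ε_i ~ N(0,1) prior the per-respondent posteriors retain a
large spread even when the data are homogeneous: a dense-grid oracle (items
fixed at truth, K = 20, ε ≡ 1) puts the spread of posterior-mean ε̂ at
S ≈ 0.8 — which would make the S_ε̂ selection rule useless, selecting
heterogeneity on every dataset. With the learned σ_ε the shrinkage adapts:
homogeneous data collapse σ_ε and drive S_ε̂ toward zero, heterogeneous data
keep σ_ε near its generating value and S_ε̂ clearly positive — the behaviour
the selection rule is built on. The fixed prior remains available via
`PriorSpec(eps_hierarchical=False)`.

The estimator is a component-wise adaptive random-walk Metropolis-within-
Gibbs sampler, written for this package. Gradient-based sampling is
unnecessary at these dimensions: every θ_i (and ln ε_i) is conditionally
independent given the item parameters, and every b_j / ln σ_j / ln a_j given
the respondent parameters, so each block is proposed and accepted
elementwise in one vectorised sweep (a fused numba kernel evaluates the
pointwise log-likelihood; a pure-NumPy path is kept as fallback). Scale
parameters are updated on the log scale and therefore never leave (0, ∞).
Per-component proposal SDs adapt by Robbins–Monro (γ_t = (t+1)^(−0.6))
toward a 0.44 acceptance rate during burn-in only; frozen step sizes keep
the retained chains Markovian. Chains start from over-dispersed prior draws
(scales inflated ×2 on the unconstrained scale), distinct per chain and
reproducible from (seed, chain index).

The (ε, σ_ε) hierarchy forms a funnel that centred component-wise updates
traverse slowly (on homogeneous data the collapsed-σ_ε region was not
reached within the reduced protocol; split-chain R̂ flagged it). The sampler
therefore interweaves a non-centred move each iteration: holding the
standardised residuals z_i = ln ε_i / σ_ε fixed, it proposes a new σ_ε and
rescales every ln ε_i with it in a single accept/reject step (likelihood +
half-Cauchy prior + log-scale Jacobian; the z_i prior is free of σ_ε in the
non-centred parameterisation). This ancillarity–sufficiency interweaving
restores R̂ < 1.05 at the reduced protocol and leaves the stationary
distribution unchanged.

Point estimates: location parameters (θ, b) are EAP posterior means; the
positive-scale parameters (ε, σ, a) are posterior medians. Their marginals
are lognormal-like and, for weakly informed respondents, the posterior-mean
ε̂ is dominated by the right tail — enough to inflate S_ε̂ and break its
shrinkage property (S_ε̂ ≤ S_ε). The median is tail-robust and preserves
both properties.

Defaults: 10,000 iterations, 5,000 burn-in, three chains
(`SamplerConfig()`); recovery runs and tests use the reduced profile of
4,000 iterations / 2,000 burn-in over two chains (`SamplerConfig.reduced()`),
which the detailed-balance and recovery checks show is converged for the
problem sizes used here. Convergence is screened by the split-chain
potential scale reduction factor (Brooks–Gelman corrected form) with
threshold 1.2; non-convergence is reported, never raised, and replications
whose maximum R̂ exceeds the threshold are flagged in study output rather
than dropped. Point estimates are EAP: posterior means over pooled
post-burn-in draws, with ε̂ and σ̂ averaged on the positive scale.

Degenerate inputs: all-0/all-1 rows or columns are allowed with a warning
(the priors regularise them); probabilities that numerically collapse to
0/1 against the observed score contribute −∞ to the likelihood and are
counted; likelihood evaluation clamps p to [1e−12, 1−1e−12]. Every
log-scale parameter is truncated to ±30 (scales in [e⁻³⁰, e³⁰]): for a
respondent whose pattern is maximally inconsistent the likelihood is flat
in ε → ∞, and on very small matrices the heavy-tailed hyperprior then lets
ln ε random-walk past float range; the bound is unreachable for realistic
posteriors and only prevents overflow in that degenerate regime.

## Fit indices and model selection

* −2LL is the deviance at the EAP point estimates (a transparent,
  reproducible choice; a plug-in, not a posterior summary).
* WAIC = −2 Σ_cells [ ln mean_s exp(ll_s) − var_s(ll_s) ], computed from a
  draws × cells pointwise log-likelihood table (thinned to ≤ 500 draws).
* LOO uses Pareto-smoothed importance sampling (arviz's `psislw` supplies
  the smoothing); cells with tail index k > 0.7 are counted as unstable.
  Both criteria are reported on the deviance scale.
* S_ε̂ is the population standard deviation (divisor N) of the EAP ε̂
  values. The selection rule chooses the IREM when S_ε̂ exceeds a threshold,
  defaulting to 0.1 — a heuristic chosen once from the separation between
  the near-zero values seen on homogeneous data and the clearly positive
  values on heterogeneous data; `s_eps_null_quantile` offers a
  parametric-bootstrap calibration (refit on homogeneous simulated data,
  take the 95th percentile of the null S_ε̂) for users who want a
  data-driven cutoff. Because of shrinkage, S_ε̂ underestimates the
  generating S_ε; the rule only needs separation from zero, not an unbiased
  estimate.

## Synthetic data generator

The generator emulates the recovery-study conditions: θ ~ N(0,1),
b ~ N(0,1), ln σ ~ N(0,1), and either ε ≡ 1 (homogeneous; paired with the
classic 2PL process, whose slopes are a = 1/σ) or ln ε ~ N(0,1)
(heterogeneous IREM process). Responses are Bernoulli draws from the
logistic IRF with D = 1.7 — the same link the estimator uses; the ogive link
is available behind `IRFConfig(link="ogive")` for sensitivity checks. The
full design is the 3×3×2 grid {200, 500, 1000} × {20, 30, 50} × {2PL, IREM}
with 30 replications per cell; respondent and item parameters are redrawn
every replication (held-fixed truth is possible by reusing a
`RespondentParams`/`ItemParams` pair). One master seed spawns per-condition
and per-replication substreams through `numpy.random.SeedSequence`, so
studies are bit-reproducible without storing matrices.

What the generator does **not** emulate: missing responses, polytomous
categories, response styles or response times, multidimensionality, and
respondent×item interactions beyond the variance mechanism. Passing
recovery tests therefore show that the estimator recovers parameters *under
the model's own assumptions*; they do not validate the model against real
questionnaire behaviour.

## Recovery study and problem sizes

Metrics are computed per replication against that replication's generating
truth, then averaged (the standard convention; recorded in the study
metadata). RMSE and bias refer to EAP θ̂; corr(ε, ε̂) is Pearson. Because
the average generating slope at ε² = σ² = 1 is 1/√2 ≈ 0.71, item
information is modest and θ RMSE stays above 0.3 even at K = 50 — the floor
is a property of the design, not an estimator defect. S_ε̂ per condition is
aggregated by mean over replications.

The package's test/acceptance profile runs a reduced grid — N = 200,
K ∈ {20, 50}, both generators, 5 replications, reduced sampler — and the
ε-recovery runs at N = 500, K ∈ {20, 50}. These sizes reproduce the
reference cells at Monte-Carlo tolerance; the full 18-cell, 30-replication
design is available through `condition_grid()` / `iremirt study --profile
full` as a long-running target.

## Questionnaire preprocessing

Four-category frequency items ("never" … "very often") are dichotomised
after orienting codes so higher means more frequent: "very often" and
"regularly" → 1, "sometimes" and "never" → 0. The loader is a generic
Likert-CSV reader; no survey data ships with the package, so full-survey
results (fit-index tables, the S_ε̂ = 0.21 decision on the parental-support
scale) are documented manual checks requiring the user-supplied CSV. The
packaged `table4.csv` carries only the three published example response
patterns.

## Known limitations

* ε_i is weakly informed by short tests; its EAP is strongly shrunk, so
  corr(ε, ε̂) is moderate (≈ 0.55 at K = 20, rising with K) and S_ε̂
  understates S_ε.
* The ε²/σ² split is prior-identified only (see Identifiability).
* Random-walk MH needs more iterations than NUTS for the same effective
  sample size; the defaults are calibrated for the N ≤ 1000, K ≤ 50 regime.
* No missing-data handling: matrices must be complete.
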