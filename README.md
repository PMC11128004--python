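# iremirt

Bayesian item response theory with **individual random effects**: a
dichotomous IRT model in which every respondent carries a within-person
variance alongside the usual latent ability.

## The problem

Classic IRT (1PL/2PL) assumes respondents with the same ability θ have the
same probability of endorsing an item. Questionnaire data routinely violate
this: two people with equal θ can show very different response patterns.
The individual random effects model (IREM) attributes that difference to a
respondent-specific *within-person* variance ε²: the momentary trait
θ\* ~ N(θ, ε²) is compared against an item threshold η ~ N(b, σ²), and the
endorsement probability is

    P(Y = 1 | θ, b, ε, σ) = Φ( (θ − b) / √(ε² + σ²) )
                          ≈ 1 / (1 + exp(−1.7 (θ − b) / √(ε² + σ²)))

so the effective item slope is 1/√(ε² + σ²). With ε constant this is
exactly the 2PL (a = 1/σ): the IREM is a strict generalisation. Whether the
generalisation is needed is decided from **S_ε̂**, the population standard
deviation of the estimated ε̂ values — near zero means a classic model
suffices; clearly positive means within-person variances differ.

The package is aimed at psychometricians and methodologists who want to
estimate the model on binary (or dichotomised 4-category Likert) response
matrices, compare it against 1PL/2PL baselines with −2LL / WAIC / PSIS-LOO,
and run seeded parameter-recovery simulations.

## What's inside

| module | contents |
| --- | --- |
| `iremirt.irf` | closed-form IRFs (ogive + logistic), the D = 1.7 approximation bound, Bernoulli log-likelihood |
| `iremirt.datagen` | seeded generators: θ, b ~ N(0,1); ln σ, ln ε ~ N(0,1) or ε ≡ 1; Bernoulli response matrices; the 18-cell study grid |
| `iremirt.sampler` | adaptive Metropolis-within-Gibbs MCMC for 1PL/2PL/IREM, split-chain R̂, EAP estimates |
| `iremirt.fit_select` | −2LL, WAIC, PSIS-LOO, S_ε̂ and the model-selection rule |
| `iremirt.study` | Monte-Carlo recovery driver: RMSE, bias, corr(ε, ε̂) |
| `iremirt.interface` | CSV/JSON/YAML I/O, Likert dichotomisation, manifests |
| `iremirt.cli` | `iremirt simulate | fit | indices | select | study` |

## Worked example

```python
import numpy as np
import iremirt as ir

rng = np.random.default_rng(42)
resp  = ir.draw_respondents(300, ir.EpsMode.LOGNORMAL, rng)   # ln eps ~ N(0,1)
items = ir.draw_items(20, rng)                                 # b, ln sigma ~ N(0,1)
Y = ir.simulate_matrix(resp, items, ir.GeneratorKind.IREM, seed=rng)

cfg = ir.SamplerConfig.reduced(seed=42)        # 4,000 iter / 2,000 burn-in, 2 chains
draws = ir.fit(Y, ir.Model.IREM, config=cfg)
est, _ = ir.point_estimates(draws)

print("max R-hat:", round(ir.rhat(draws).max_rhat, 3))
print("theta RMSE vs truth:", round(ir.rmse(est.theta, resp.theta), 3))
print("corr(eps-hat, eps):", round(ir.corr_eps(est.eps, resp.eps), 3))

fi   = ir.fit_indices(Y, draws)
fi2  = ir.fit_indices(Y, ir.fit(Y, ir.Model.TWO_PL, config=cfg))
print(ir.select_model({"IREM": fi, "2PL": fi2}).rationale)
```

Output:

```
max R-hat: 1.05
theta RMSE vs truth: 0.492
corr(eps-hat, eps): 0.639
S_eps-hat = 1.592 > 0.1: within-person variances differ across respondents;
the individual random effects model is retained.
WAIC by model: {'IREM': 6645.2, '2PL': 6840.1}.
```

Reading the numbers: R̂ < 1.2 shows no sign of non-convergence; θ RMSE ≈ 0.49
is expected at K = 20 because the average generating slope is only
1/√2 ≈ 0.71; ε̂ correlates moderately with the generating ε (short tests
carry little information about a respondent's variance); and S_ε̂ ≫ 0
correctly identifies the heterogeneous generating process, corroborated by
the IREM's lower WAIC.

The same pipeline is available from the shell:

```sh
iremirt simulate --model irem -N 300 -K 20 --seed 42 --out sim.csv
iremirt fit sim.csv --model irem --seed 42 --out-prefix fit
iremirt indices sim.csv --model irem --seed 42 --out irem.json
iremirt study --profile ci --seed 0
```

Real Likert data (e.g. a 4-category frequency scale) enters through
`read_likert_csv` + `dichotomize`, which recode "very often"/"regularly" to
1 and "sometimes"/"never" to 0 after orienting the codes.

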