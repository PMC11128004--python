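"""Shared fixtures: small fitted models and the scaled-down recovery runs.

The heavy session fixtures are lazy — only tests that request them trigger
the MCMC runs — and seeded so every session reproduces the same numbers.
"""

import numpy as np
import pytest

import iremirt as ir

SEED = 0


@pytest.fixture(scope="session")
def small_irem_data():
    """An 80 x 12 IREM-generated dataset with its generating truth."""
    rng = np.random.default_rng(7)
    resp = ir.draw_respondents(80, ir.EpsMode.LOGNORMAL, rng)
    items = ir.draw_items(12, rng)
    Y = ir.simulate_matrix(resp, items, ir.GeneratorKind.IREM, seed=rng)
    return Y, resp, items


@pytest.fixture(scope="session")
def small_irem_fit(small_irem_data):
    """A quick two-chain IREM fit on the small dataset."""
    Y, _, _ = small_irem_data
    cfg = ir.SamplerConfig(iterations=1500, burn_in=750, chains=2, seed=7)
    return ir.fit(Y, ir.Model.IREM, config=cfg)


@pytest.fixture(scope="session")
def reduced_study():
    """The scaled-down recovery study: N=200, K in {20, 50}, both generators, 5 reps."""
    grid = ir.reduced_grid(master_seed=SEED, reps=5)
    return ir.run_study(grid, sampler_config=ir.SamplerConfig.reduced(seed=SEED))


@pytest.fixture(scope="session")
def eps_recovery_runs():
    """IREM fits on IREM-generated data at N=500, K in {20, 50}, 5 reps each.

    Returns per-replication corr(eps-hat, eps), S_eps-hat and the generating
    S_eps, keyed by test length.
    """
    out = {}
    for K in (20, 50):
        recs = []
        for child in np.random.SeedSequence([SEED, K]).spawn(5):
            rng = np.random.default_rng(child)
            resp = ir.draw_respondents(500, ir.EpsMode.LOGNORMAL, rng)
            items = ir.draw_items(K, rng)
            Y = ir.simulate_matrix(resp, items, ir.GeneratorKind.IREM, seed=rng)
            cfg = ir.SamplerConfig.reduced(seed=int(child.generate_state(1)[0] % 2**31))
            draws = ir.fit(Y, ir.Model.IREM, config=cfg)
            eps_hat, _ = ir.point_estimates(draws)
            recs.append(
                {
                    "corr": ir.corr_eps(eps_hat.eps, resp.eps),
                    "s_hat": ir.s_eps_hat(eps_hat.eps),
                    "s_true": ir.s_eps_hat(resp.eps),
                }
            )
        out[K] = recs
    return out
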