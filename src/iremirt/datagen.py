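"""Seeded synthetic data generation for the parameter-recovery experiments.

The generating distributions mirror the study conditions: abilities
theta ~ N(0, 1), difficulties b ~ N(0, 1), log item threshold SDs
ln sigma ~ N(0, 1), and within-person SDs either identically 1 (the
constant-variance regime) or ln eps ~ N(0, 1) (heterogeneous).  Both study
regimes share the combined-variance response function, so the constant
regime is exactly a 2PL with slopes 1/sqrt(1 + sigma_j^2) — average slope
about 0.71 — which is why it is labelled the 2PL process.
:func:`simulate_matrix` also accepts classic slope-based generation
(eps plays no role; P uses a_j directly) for plain 1PL/2PL simulation.
Response matrices are Bernoulli draws from the logistic item response
function with D = 1.7, matching the link used by the estimator.

A single master seed deterministically spawns per-condition and
per-replication substreams via :class:`numpy.random.SeedSequence`, so a full
study is reproducible without storing any matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Union

import numpy as np

from .irf import (
    IRFConfig,
    InvalidParameterError,
    ItemParams,
    RespondentParams,
    ResponseMatrix,
    prob_matrix,
)

__all__ = [
    "GeneratorKind",
    "EpsMode",
    "SimulationCondition",
    "FixtureSet",
    "TABLE4_FIXTURE",
    "draw_respondents",
    "draw_items",
    "simulate_matrix",
    "condition_grid",
    "REPLICATIONS_DEFAULT",
]

#: Replications per simulation condition in the full study design.
REPLICATIONS_DEFAULT = 30

#: Factor levels of the full simulation grid.
SAMPLE_SIZES = (200, 500, 1000)
TEST_LENGTHS = (20, 30, 50)


class GeneratorKind(str, Enum):
    """Which process generates the response matrix."""

    ONE_PL = "1PL"
    TWO_PL = "2PL"
    IREM = "IREM"


class EpsMode(str, Enum):
    """Within-person SD regime: constant (classic) or lognormal (IREM)."""

    CONSTANT_ONE = "constant_one"
    LOGNORMAL = "lognormal"


def _rng(seed: Union[int, np.random.Generator, np.random.SeedSequence]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design."""

    N: int
    K: int
    generator: GeneratorKind
    eps_mode: EpsMode
    reps: int = REPLICATIONS_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1 or self.K < 1 or self.reps < 1:
            raise InvalidParameterError("N, K and reps must all be >= 1")
        constant = self.eps_mode is EpsMode.CONSTANT_ONE
        classic = self.generator is not GeneratorKind.IREM
        if constant != classic:
            raise InvalidParameterError(
                "CONSTANT_ONE pairs with the classic generator, LOGNORMAL with IREM"
            )


def draw_respondents(
    N: int,
    eps_mode: EpsMode = EpsMode.LOGNORMAL,
    seed: Union[int, np.random.Generator] = 0,
) -> RespondentParams:
    """Draw respondent parameters: theta ~ N(0,1); eps per ``eps_mode``.

    CONSTANT_ONE sets every eps to exactly 1 (the homogeneous-variance,
    classic-IRT regime); LOGNORMAL draws ln eps ~ N(0, 1).
    """
    if N < 1:
        raise InvalidParameterError("N must be >= 1")
    rng = _rng(seed)
    theta = rng.standard_normal(N)
    if eps_mode is EpsMode.CONSTANT_ONE:
        eps = np.ones(N)
    else:
        eps = np.exp(rng.standard_normal(N))
    return RespondentParams(theta=theta, eps=eps)


def draw_items(K: int, seed: Union[int, np.random.Generator] = 0) -> ItemParams:
    """Draw item parameters: b ~ N(0,1), ln sigma ~ N(0,1), a = 1/sigma."""
    if K < 1:
        raise InvalidParameterError("K must be >= 1")
    rng = _rng(seed)
    b = rng.standard_normal(K)
    sigma = np.exp(rng.standard_normal(K))
    return ItemParams(b=b, sigma=sigma)


def simulate_matrix(
    resp: RespondentParams,
    items: ItemParams,
    generator: GeneratorKind = GeneratorKind.IREM,
    config: IRFConfig = IRFConfig(),
    seed: Union[int, np.random.Generator] = 0,
) -> ResponseMatrix:
    """Sample y_ij ~ Bernoulli(P_ij) independently from the chosen process.

    IREM uses the within-person SDs in ``resp.eps`` together with the item
    threshold SDs; the classic generators use the slopes ``items.a``.
    """
    if generator is GeneratorKind.IREM and resp.eps is None:
        raise InvalidParameterError("IREM generation requires eps")
    model = "IREM" if generator is GeneratorKind.IREM else "2PL"
    P = prob_matrix(resp, items, model=model, config=config)
    rng = _rng(seed)
    scores = (rng.random(P.shape) < P).astype(np.int8)
    return ResponseMatrix(scores=scores)


def condition_grid(
    master_seed: int = 0, reps: int = REPLICATIONS_DEFAULT
) -> List[SimulationCondition]:
    """The full 3 x 3 x 2 study grid with per-cell derived seeds.

    Sample sizes {200, 500, 1000} x test lengths {20, 30, 50} x generating
    process {2PL, IREM}, each cell carrying its own substream seed spawned
    from ``master_seed``.
    """
    cells = [
        (N, K, gen)
        for N in SAMPLE_SIZES
        for K in TEST_LENGTHS
        for gen in (GeneratorKind.TWO_PL, GeneratorKind.IREM)
    ]
    children = np.random.SeedSequence(master_seed).spawn(len(cells))
    grid = []
    for (N, K, gen), child in zip(cells, children):
        eps_mode = EpsMode.CONSTANT_ONE if gen is GeneratorKind.TWO_PL else EpsMode.LOGNORMAL
        grid.append(
            SimulationCondition(
                N=N,
                K=K,
                generator=gen,
                eps_mode=eps_mode,
                reps=reps,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        )
    return grid


# ---------------------------------------------------------------------------
# Printed fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSet:
    """Small response patterns packaged for worked examples and tests."""

    table4_patterns: "ResponseMatrix" = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.table4_patterns is None:
            object.__setattr__(self, "table4_patterns", _table4())


def _table4() -> ResponseMatrix:
    """Three 10-item response patterns of respondents sharing the same EAP ability.

    The three respondents endorse 6, 7 and 5 items respectively yet receive
    the same ability estimate under the IREM; the difference in pattern is
    absorbed by their within-person SDs.
    """
    patterns = {
        "P371": "1101010101",
        "P2754": "1111110001",
        "P3716": "0010011101",
    }
    scores = np.array([[int(c) for c in row] for row in patterns.values()], dtype=np.int8)
    return ResponseMatrix(
        scores=scores,
        respondent_ids=list(patterns),
        item_ids=[f"Item{j}" for j in range(1, 11)],
    )


TABLE4_FIXTURE = FixtureSet()
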