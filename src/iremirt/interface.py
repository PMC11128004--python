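"""File I/O, Likert dichotomisation, run configuration and manifests.

CSV dialect is fixed for bit-exact reproducibility across locales: UTF-8,
comma separator, "." decimal, mandatory header row of item ids and a first
column of respondent ids.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .irf import InvalidParameterError, ItemParams, RespondentParams, ResponseMatrix

__all__ = [
    "LikertMatrix",
    "RunConfig",
    "LIKERT_LABELS",
    "read_response_csv",
    "write_response_csv",
    "read_likert_csv",
    "dichotomize",
    "write_params_json",
    "read_params_json",
    "write_draws_csv",
    "write_manifest",
    "load_run_config",
    "table4_path",
]

logger = logging.getLogger("iremirt")

#: Frequency categories in increasing order of endorsement frequency.
LIKERT_LABELS = ("never", "sometimes", "regularly", "very often")

#: Categories recoded to 1 (higher frequency); the rest map to 0.
_HIGH_FREQUENCY = {"very often", "regularly"}


@dataclass
class LikertMatrix:
    """N x K four-category frequency codes with an orientation flag.

    ``codes`` take values 1..4.  ``higher_is_more_frequent`` states whether a
    larger code means higher frequency; if False the matrix is reverse-coded
    before dichotomisation (questionnaire exports often code 1 = "very
    often").
    """

    codes: np.ndarray
    higher_is_more_frequent: bool = True
    respondent_ids: Optional[Sequence[str]] = None
    item_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.codes = np.atleast_2d(np.asarray(self.codes))
        bad = ~np.isin(self.codes, (1, 2, 3, 4))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise InvalidParameterError(
                f"Likert codes must lie in 1..4; offending cell (row {r}, col {c}) "
                f"= {self.codes[r, c]!r}"
            )
        self.codes = self.codes.astype(np.int8)

    def labels(self) -> np.ndarray:
        """Category label of every cell after orienting codes to frequency order."""
        codes = self.codes if self.higher_is_more_frequent else 5 - self.codes
        return np.asarray(LIKERT_LABELS, dtype=object)[codes - 1]


def dichotomize(L: LikertMatrix) -> ResponseMatrix:
    """Recode a four-category frequency matrix to binary scores.

    After reverse-coding so that higher codes mean higher frequency,
    "very often" and "regularly" become 1 and "sometimes"/"never" become 0.
    Idempotent on the induced binary labels: re-applying the rule to the
    relabelled output changes nothing.
    """
    labels = L.labels()
    unknown = ~np.isin(labels, LIKERT_LABELS)
    if unknown.any():
        raise InvalidParameterError(f"unknown category label {labels[unknown][0]!r}")
    scores = np.isin(labels, list(_HIGH_FREQUENCY)).astype(np.int8)
    return ResponseMatrix(
        scores=scores, respondent_ids=L.respondent_ids, item_ids=L.item_ids
    )


# ---------------------------------------------------------------------------
# CSV / JSON round-trips
# ---------------------------------------------------------------------------


def read_response_csv(path: Union[str, Path]) -> ResponseMatrix:
    """Read a binary response CSV (header = item ids, first column = respondent ids).

    Validation failures name the offending cells by row and column id.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise InvalidParameterError(f"empty or missing response file: {path}")
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise InvalidParameterError(f"no data rows/columns in {path}")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise InvalidParameterError(f"duplicate respondent or item ids in {path}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise InvalidParameterError(
            f"missing cell at respondent {df.index[r]!r}, item {df.columns[c]!r} in {path}"
        )
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise InvalidParameterError(
            f"non-binary cell {values[r, c]!r} at respondent {df.index[r]!r}, "
            f"item {df.columns[c]!r} in {path}"
        )
    return ResponseMatrix(
        scores=values.astype(np.int8),
        respondent_ids=[str(i) for i in df.index],
        item_ids=[str(c) for c in df.columns],
    )


def write_response_csv(Y: ResponseMatrix, path: Union[str, Path]) -> None:
    """Write a response matrix in the canonical CSV layout."""
    df = pd.DataFrame(Y.scores, index=list(Y.respondent_ids), columns=list(Y.item_ids))
    df.to_csv(path, lineterminator="\n")


def read_likert_csv(
    path: Union[str, Path], higher_is_more_frequent: bool = True
) -> LikertMatrix:
    """Read a four-category Likert CSV in the same layout as the response CSV."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise InvalidParameterError(f"empty or missing Likert file: {path}")
    df = pd.read_csv(path, index_col=0)
    return LikertMatrix(
        codes=df.to_numpy(),
        higher_is_more_frequent=higher_is_more_frequent,
        respondent_ids=[str(i) for i in df.index],
        item_ids=[str(c) for c in df.columns],
    )


def write_params_json(
    resp: Optional[RespondentParams], items: Optional[ItemParams], path: Union[str, Path]
) -> None:
    """Persist a parameter set as JSON."""
    payload: Dict[str, object] = {}
    if resp is not None:
        payload["respondents"] = {"theta": resp.theta.tolist(), "eps": resp.eps.tolist()}
    if items is not None:
        payload["items"] = {
            "b": items.b.tolist(),
            "sigma": items.sigma.tolist(),
            "a": items.a.tolist(),
        }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_params_json(path: Union[str, Path]):
    """Inverse of :func:`write_params_json`; returns (RespondentParams | None, ItemParams | None)."""
    payload = json.loads(Path(path).read_text())
    resp = items = None
    if "respondents" in payload:
        resp = RespondentParams(
            theta=np.asarray(payload["respondents"]["theta"]),
            eps=np.asarray(payload["respondents"]["eps"]),
        )
    if "items" in payload:
        items = ItemParams(
            b=np.asarray(payload["items"]["b"]),
            sigma=np.asarray(payload["items"]["sigma"]),
        )
    return resp, items


def write_draws_csv(draws, path: Union[str, Path]) -> None:
    """Columnar draw export: one column per scalar parameter, chain id column."""
    frames = []
    for c in range(draws.n_chains):
        cols: Dict[str, np.ndarray] = {"chain": np.full(draws.n_draws, c)}
        for name, arr in draws.params.items():
            block = arr[c]
            if block.ndim == 1:
                cols[name] = block
            else:
                for j in range(block.shape[1]):
                    cols[f"{name}[{j + 1}]"] = block[:, j]
        frames.append(pd.DataFrame(cols))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, lineterminator="\n")


def write_manifest(path: Union[str, Path], config: Dict[str, object]) -> None:
    """Run manifest: package version, config hash, and the config itself."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "config": json.loads(blob),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_ALLOWED_MODELS = {"1PL", "2PL", "IREM"}


@dataclass
class RunConfig:
    """Validated YAML run configuration for the CLI."""

    model: str = "IREM"
    seed: int = 0
    iterations: int = 10_000
    burn_in: int = 5_000
    chains: int = 3
    D: float = 1.7
    s_threshold: float = 0.1
    input_path: Optional[str] = None
    output_dir: str = "."
    study_reps: int = 5
    extras: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model.upper() not in _ALLOWED_MODELS:
            raise InvalidParameterError(f"model must be one of {_ALLOWED_MODELS}")
        if not 0 <= self.burn_in < self.iterations:
            raise InvalidParameterError("require 0 <= burn_in < iterations")
        if self.chains < 1 or self.study_reps < 1:
            raise InvalidParameterError("chains and study_reps must be >= 1")
        if self.D <= 0:
            raise InvalidParameterError("D must be > 0")


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration before any computation."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extras"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extras = {k: v for k, v in raw.items() if k not in known}
    return RunConfig(**kwargs, extras=extras)


def table4_path() -> Path:
    """Path of the packaged three-respondent worked-example CSV."""
    return Path(__file__).parent / "data" / "table4.csv"
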