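"""Criterion flags, AUD index, AUD score and the prone/resistant split.

An animal is *positive for an AUD-like criterion* when its index in a test
lies in the uppermost 35% of the population.  The **AUD index** counts
fulfilled criteria (0-5); animals with >= 2 criteria are classified
**AUD-prone**, the rest **AUD-resistant**.  The continuous **AUD score**
(AS) sums population z-scores over the behaviors:
``AS_i = sum_b (V_ib - mean_b) / SD_b``.

Quantile rule: the per-behavior threshold is the nearest-rank (1-q)-quantile
(the ceil((1-q)*n)-th smallest value) and an animal is flagged only when
*strictly greater* than the threshold — with all-distinct values and q*n
integral this flags exactly q*n animals, and animals tied with the threshold
are never flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavioral_indices import BEHAVIOR_NAMES, BehaviorMatrix
from .errors import ConfigError, DegenerateColumnWarning, ScoringError


@dataclass(frozen=True)
class ScoringConfig:
    criterion_quantile: float = 0.35
    criteria_threshold: int = 2
    behaviors_used: tuple[str, ...] = BEHAVIOR_NAMES
    sd_ddof: int = 1  # sample SD (n-1) in the z-scores

    def validate(self) -> "ScoringConfig":
        if not 0.0 < self.criterion_quantile < 1.0:
            raise ConfigError("criterion_quantile must lie in (0, 1)")
        if not 1 <= self.criteria_threshold <= len(self.behaviors_used):
            raise ConfigError("criteria_threshold must lie in "
                              "[1, number of behaviors]")
        unknown = set(self.behaviors_used) - set(BEHAVIOR_NAMES)
        if unknown:
            raise ConfigError(f"unknown behavior(s): {sorted(unknown)}")
        return self


@dataclass
class AUDResult:
    """Per-animal flags, AUD index, AUD score and class label."""

    table: pd.DataFrame  # animal_id, flag_*, aud_index, aud_score, class

    @property
    def prone_fraction(self) -> float:
        return float((self.table["class"] == "prone").mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AUDResult":
        return cls(pd.read_csv(path, dtype={"animal_id": str}))


def nearest_rank_threshold(values: np.ndarray, q: float) -> float:
    """The ceil((1-q)*n)-th smallest value (a tiny epsilon guards against
    floating error in (1-q)*n when it is integral)."""
    n = len(values)
    rank = int(math.ceil((1.0 - q) * n - 1e-9))
    rank = min(max(rank, 1), n)
    return float(np.sort(np.asarray(values, float))[rank - 1])


def criterion_flags(matrix: BehaviorMatrix, q: float = 0.35) -> pd.DataFrame:
    """Boolean animals x behaviors table: value strictly above the
    uppermost-q nearest-rank threshold of its (direction-oriented) column."""
    if not 0.0 < q < 1.0:
        raise ConfigError("q must lie in (0, 1)")
    n = matrix.n_animals
    if n < 3:
        raise ScoringError(f"population of {n} is too small to set "
                           "quantile criteria (need >= 3 animals)")
    oriented = matrix.values * matrix.direction[np.newaxis, :]
    flags = {}
    for j, name in enumerate(matrix.behavior_names):
        col = oriented[:, j]
        if np.ptp(col) == 0.0:
            warnings.warn(
                f"behavior column {name!r} has zero variance; no animal can "
                "be positive for this criterion", DegenerateColumnWarning,
                stacklevel=2,
            )
            flags[f"flag_{name}"] = np.zeros(n, bool)
            continue
        thr = nearest_rank_threshold(col, q)
        flags[f"flag_{name}"] = col > thr
    out = pd.DataFrame(flags)
    out.insert(0, "animal_id", matrix.animal_ids)
    return out


def aud_index(flags: pd.DataFrame) -> pd.Series:
    """Number of fulfilled criteria per animal (row sum of the flags)."""
    cols = [c for c in flags.columns if c.startswith("flag_")]
    return flags[cols].sum(axis=1).astype(int)


def classify(index: int | np.ndarray | pd.Series, k: int = 2):
    """'prone' iff the AUD index is >= k (default 2), else 'resistant'."""
    arr = np.asarray(index)
    out = np.where(arr >= k, "prone", "resistant")
    if arr.ndim == 0:
        return str(out)
    return out


def aud_score(matrix: BehaviorMatrix,
              behaviors_used: tuple[str, ...] | None = None,
              ddof: int = 1) -> pd.Series:
    """Z-sum AUD score: sum over behaviors of (value - mean) / SD, with
    columns oriented by the matrix's direction metadata."""
    if matrix.n_animals < 3:
        raise ScoringError("population too small for z-scoring (need >= 3)")
    used = behaviors_used or matrix.behavior_names
    oriented = matrix.values * matrix.direction[np.newaxis, :]
    total = np.zeros(matrix.n_animals)
    for name in used:
        j = matrix.behavior_names.index(name)
        col = oriented[:, j]
        sd = col.std(ddof=ddof)
        if sd == 0.0:
            raise ScoringError(f"behavior column {name!r} has zero SD; "
                               "cannot z-score")
        total += (col - col.mean()) / sd
    return pd.Series(total, name="aud_score")


def score_cohort(matrix: BehaviorMatrix,
                 config: ScoringConfig | None = None) -> AUDResult:
    """Full scoring: flags, AUD index, AUD score, class label."""
    cfg = (config or ScoringConfig()).validate()
    flags = criterion_flags(matrix, cfg.criterion_quantile)
    idx = aud_index(flags)
    score = aud_score(matrix, cfg.behaviors_used, cfg.sd_ddof)
    table = flags.copy()
    table["aud_index"] = idx
    table["aud_score"] = score.to_numpy()
    table["class"] = classify(idx.to_numpy(), cfg.criteria_threshold)
    return AUDResult(table=table)
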