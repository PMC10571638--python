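"""The five per-animal behavioral indices of the AUD phenotyping battery.

From phase-sliced event logs this module computes, per animal:

* **M** — motivation: the fixed-ratio (FR) requirement reached in the
  progressive-ratio test, where the nosepoke requirement climbs a ladder
  (2, 4, 8, 12, 16, 20, 24, 28, 32, 36) after 10 completed sets per level and
  a "set" is a burst of requirement-many pokes spaced by less than 1 s within
  one visit;
* **E** — extinction: average daily reward-corner nosepokes over the 7-day
  extinction (plus the difference from the last pre-extinction day);
* **CR** — cue relapse: reward-corner nosepokes during the 24-h cue test
  (plus the difference from the last extinction day);
* **AR** — alcohol relapse: alcohol consumed on the first relapse day in
  g/kg/day, from lick counts via the lick-volume calibration
  (licks x lick volume x alcohol fraction x 1 g/ml / body weight);
* **P** — persistence: reward-corner nosepokes during the non-active (nA)
  6-h periods of the 3-day persistence test (plus the nA - A difference).

All five are oriented so that larger = more AUD-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AnimalLookupError,
    CompletenessWarning,
    ConfigError,
    DomainError,
    ScheduleError,
)
from .event_model import DAY_S, EventLog, resolve_window, slice_interval, slice_phase

#: Cohort-wide average lick volume used when no calibration data are supplied
#: (microliters per lick).
DEFAULT_LICK_VOLUME_UL = 1.94

BEHAVIOR_NAMES = ("M", "E", "CR", "AR", "P")

_SPAN_TOL_S = 1.0


@dataclass(frozen=True)
class RatioLadder:
    """Progressive-ratio schedule: poke requirements and advancement rule."""

    steps: tuple[int, ...] = (2, 4, 8, 12, 16, 20, 24, 28, 32, 36)
    sets_to_advance: int = 10
    max_intra_burst_gap_s: float = 1.0
    reward_access_s: float = 5.0

    def validate(self) -> "RatioLadder":
        if len(self.steps) == 0:
            raise ConfigError("ratio ladder must have at least one step")
        if any(s <= 0 for s in self.steps):
            raise ConfigError("ladder steps must be positive integers")
        if any(b <= a for a, b in zip(self.steps, self.steps[1:])):
            raise ConfigError("ladder steps must be strictly increasing")
        if self.sets_to_advance < 1:
            raise ConfigError("sets_to_advance must be >= 1")
        return self


@dataclass
class BehaviorMatrix:
    """Animals x 5 behavioral indices, plus alternate index variants.

    ``direction`` is +1 for every column: all indices are already oriented so
    that larger values are more AUD-like.  ``alternates`` carries the full
    index table (M, E, E_delta, CR, CR_delta, AR, P, P_delta);
    ``completeness`` maps excluded animals to the phases they were missing
    from.
    """

    animal_ids: list[str]
    values: np.ndarray  # shape (n, 5)
    behavior_names: tuple[str, ...] = BEHAVIOR_NAMES
    direction: np.ndarray = field(default_factory=lambda: np.ones(5))
    alternates: pd.DataFrame | None = None
    completeness: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.behavior_names))
        df.insert(0, "animal_id", self.animal_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BehaviorMatrix":
        missing = [c for c in ("animal_id",) + BEHAVIOR_NAMES if c not in df.columns]
        if missing:
            raise ConfigError(f"behavior matrix missing column(s): {missing}")
        values = df[list(BEHAVIOR_NAMES)].to_numpy(float)
        if np.isnan(values).any():
            raise ConfigError("behavior matrix contains missing values")
        return cls(animal_ids=[str(a) for a in df["animal_id"]], values=values,
                   alternates=df.copy())

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)


# ---------------------------------------------------------------------- #
# helpers
# ---------------------------------------------------------------------- #

def _require_animal(log: EventLog, animal_id: str) -> None:
    if animal_id not in set(log.registry["animal_id"]):
        raise AnimalLookupError(f"animal {animal_id!r} not in registry")


def _reward_events(log: EventLog, animal_id: str, kind: str) -> pd.DataFrame:
    ev = log.events
    m = ((ev["animal_id"] == animal_id) & (ev["kind"] == kind)
         & (ev["corner"] == "reward"))
    return ev[m]


def _check_span(log: EventLog, phase: str | None, days: float, what: str
                ) -> tuple[float, float]:
    start, end = resolve_window(log, phase)
    if abs((end - start) - days * DAY_S) > _SPAN_TOL_S:
        raise ScheduleError(
            f"{what} slice must span {days:g} daily bin(s), got "
            f"{(end - start) / DAY_S:g} days"
        )
    return start, end


# ---------------------------------------------------------------------- #
# M: progressive-ratio breakpoint
# ---------------------------------------------------------------------- #

def compute_breakpoint(log: EventLog, animal_id: str,
                       ladder: RatioLadder | None = None,
                       mode: str = "requirement") -> int:
    """Replay the motivation-phase nosepokes and return the FR level reached.

    Pokes at the reward corner form a *burst* while consecutive inter-poke
    gaps stay below ``max_intra_burst_gap_s`` and the pokes share a visit; a
    gap of 1 s or more, or a visit boundary, resets a partial burst.  When a
    burst reaches the current requirement one set is completed and the burst
    counter resets (door-open period); after ``sets_to_advance`` sets the
    requirement advances to the next ladder value.

    ``mode="requirement"`` (default) returns the requirement in effect at the
    end of the slice — the level the animal advanced *to*; an animal that
    never completes a set returns the first ladder value.
    ``mode="last_completed"`` returns the last level at which a set was
    completed instead.
    """
    ladder = (ladder or RatioLadder()).validate()
    if mode not in ("requirement", "last_completed"):
        raise ConfigError(f"unknown breakpoint mode {mode!r}")
    _require_animal(log, animal_id)
    pokes = _reward_events(log, animal_id, "nosepoke")
    t = pokes["timestamp_s"].to_numpy()
    visit = pokes["visit_seq"].to_numpy()
    return _breakpoint_replay(t, visit, ladder, mode)


def _breakpoint_replay(t: np.ndarray, visit: np.ndarray, ladder: RatioLadder,
                       mode: str) -> int:
    order = np.argsort(t, kind="stable")
    t, visit = t[order], visit[order]

    steps = ladder.steps
    level = 0
    sets_done = 0
    burst = 0
    last_t = -np.inf
    last_visit = None
    last_completed: int | None = None
    for ti, vi in zip(t, visit):
        if vi != last_visit or (ti - last_t) >= ladder.max_intra_burst_gap_s:
            burst = 0
        burst += 1
        last_t, last_visit = ti, vi
        if burst >= steps[level]:
            sets_done += 1
            burst = 0
            last_completed = level
            if sets_done >= ladder.sets_to_advance and level < len(steps) - 1:
                level += 1
                sets_done = 0
    if mode == "last_completed":
        return steps[last_completed] if last_completed is not None else steps[0]
    return steps[level]


# ---------------------------------------------------------------------- #
# E / CR: extinction and cue-relapse seeking
# ---------------------------------------------------------------------- #

def compute_extinction_index(log: EventLog, baseline_log: EventLog,
                             animal_id: str) -> tuple[float, float]:
    """(avg daily reward nosepokes over the 7 extinction days,
    that average minus the last pre-extinction day's count)."""
    _require_animal(log, animal_id)
    _check_span(log, "extinction", 7, "extinction")
    _check_span(baseline_log, None, 1, "extinction baseline")
    total = len(_reward_events(log, animal_id, "nosepoke"))
    baseline = len(_reward_events(baseline_log, animal_id, "nosepoke"))
    avg = total / 7.0
    return avg, avg - baseline


def compute_cue_relapse_index(log: EventLog, last_ext_day_log: EventLog,
                              animal_id: str) -> tuple[float, float]:
    """(reward nosepokes in the 24-h cue test,
    that count minus the last extinction day's count)."""
    _require_animal(log, animal_id)
    _check_span(log, "cue_relapse", 1, "cue relapse")
    _check_span(last_ext_day_log, None, 1, "last extinction day")
    daily = float(len(_reward_events(log, animal_id, "nosepoke")))
    last = float(len(_reward_events(last_ext_day_log, animal_id, "nosepoke")))
    return daily, daily - last


# ---------------------------------------------------------------------- #
# AR: consumption
# ---------------------------------------------------------------------- #

def calibrate_lick_volume(total_volume_ul: float, n_licks: int) -> float:
    """Average volume of one lick (uL): total volume consumed / lick count."""
    if n_licks == 0:
        raise ZeroDivisionError(
            "lick-volume calibration requires n_licks > 0 (no licks recorded)"
        )
    if n_licks < 0 or total_volume_ul < 0:
        raise DomainError("calibration inputs must be non-negative")
    return total_volume_ul / n_licks


def compute_daily_consumption(n_licks: int, lick_volume_ul: float,
                              alcohol_fraction: float,
                              body_weight_g: float) -> float:
    """Daily alcohol intake in g/kg/day.

    licks x lick volume (ml) x alcohol volume fraction x 1 g/ml, divided by
    body weight in kg.  The 1 g/ml density convention is applied as-is.
    """
    if body_weight_g <= 0:
        raise DomainError("body_weight_g must be > 0")
    if min(n_licks, lick_volume_ul, alcohol_fraction) < 0:
        raise DomainError("consumption inputs must be non-negative")
    grams = n_licks * (lick_volume_ul * 1e-3) * alcohol_fraction * 1.0
    return grams / (body_weight_g * 1e-3)


def compute_relapse_consumption(log: EventLog, animal_id: str,
                                lick_volume_ul: float,
                                body_weight_g: float,
                                alcohol_fraction: float | None = None) -> float:
    """g/kg consumed during the first daily bin of an alcohol-relapse slice."""
    _require_animal(log, animal_id)
    start, end = resolve_window(log, "alcohol_relapse")
    if alcohol_fraction is None:
        occ = log.schedule.occurrences("alcohol_relapse")
        if not occ:
            raise ScheduleError("no alcohol_relapse window to take the "
                                "alcohol fraction from")
        alcohol_fraction = occ[0].alcohol_fraction
    day1 = slice_interval(log, start, min(start + DAY_S, end))
    n_licks = len(_reward_events(day1, animal_id, "lick"))
    return compute_daily_consumption(n_licks, lick_volume_ul, alcohol_fraction,
                                     body_weight_g)


# ---------------------------------------------------------------------- #
# P: persistence
# ---------------------------------------------------------------------- #

def compute_persistence_index(log: EventLog, animal_id: str
                              ) -> tuple[float, float]:
    """(reward nosepokes in non-active periods, nA minus A difference).

    The 3-day persistence slice is partitioned into twelve 6-h periods,
    active first (the test starts at dark-phase onset with an active period),
    alternating with non-active.
    """
    _require_animal(log, animal_id)
    start, end = _check_span(log, "persistence", 3, "persistence")
    block = (end - start) / 12.0
    pokes = _reward_events(log, animal_id, "nosepoke")
    t = pokes["timestamp_s"].to_numpy()
    idx = np.floor((t - start) / block).astype(np.int64)
    idx = np.clip(idx, 0, 11)
    na = int(np.sum(idx % 2 == 1))
    a = int(np.sum(idx % 2 == 0))
    return float(na), float(na - a)


# ---------------------------------------------------------------------- #
# assembly
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class IndexConfig:
    """Which phase occurrences are scored and which index variants enter the
    5-column matrix (defaults: first occurrences; avg/count variants)."""

    occurrence: dict[str, int] = field(default_factory=dict)
    ladder: RatioLadder = field(default_factory=RatioLadder)
    breakpoint_mode: str = "requirement"
    e_variant: str = "avg"      # "avg" | "delta"
    cr_variant: str = "daily"   # "daily" | "delta"
    p_variant: str = "na"       # "na" | "delta"

    def occ(self, phase: str) -> int:
        return self.occurrence.get(phase, 1)


def build_behavior_matrix(log: EventLog,
                          lick_volume_ul: float = DEFAULT_LICK_VOLUME_UL,
                          config: IndexConfig | None = None) -> BehaviorMatrix:
    """Score every registry animal on the five behaviors.

    Animals with no events at all in one of the five scored phase windows are
    listed in the completeness report, excluded, and a warning is emitted.
    """
    cfg = config or IndexConfig()
    ladder = cfg.ladder.validate()
    sched = log.schedule

    mot = slice_phase(log, "motivation", cfg.occ("motivation"))
    ext = slice_phase(log, "extinction", cfg.occ("extinction"))
    ext_w = sched.window("extinction", cfg.occ("extinction"))
    baseline = slice_interval(log, ext_w.start_s - DAY_S, ext_w.start_s)
    last_ext_day = slice_interval(log, ext_w.end_s - DAY_S, ext_w.end_s)
    cue = slice_phase(log, "cue_relapse", cfg.occ("cue_relapse"))
    relapse = slice_phase(log, "alcohol_relapse", cfg.occ("alcohol_relapse"))
    pers = slice_phase(log, "persistence", cfg.occ("persistence"))

    _check_span(ext, "extinction", 7, "extinction")
    _check_span(cue, "cue_relapse", 1, "cue relapse")
    p_start, p_end = _check_span(pers, "persistence", 3, "persistence")

    def _reward_counts(sl: EventLog, kind: str) -> dict[str, int]:
        ev = sl.events
        sub = ev[(ev["kind"] == kind) & (ev["corner"] == "reward")]
        g = sub.groupby("animal_id", observed=True).size()
        return {str(k): int(v) for k, v in g.items()}

    ext_np = _reward_counts(ext, "nosepoke")
    base_np = _reward_counts(baseline, "nosepoke")
    cue_np = _reward_counts(cue, "nosepoke")
    last_np = _reward_counts(last_ext_day, "nosepoke")

    # persistence: parity of the 6-h period index (active first)
    block = (p_end - p_start) / 12.0
    pev = pers.events
    ppk = pev[(pev["kind"] == "nosepoke") & (pev["corner"] == "reward")]
    parity = (np.clip(np.floor((ppk["timestamp_s"].to_numpy() - p_start)
                               / block), 0, 11).astype(np.int64) % 2)
    na_np = {str(k): int(v) for k, v in
             ppk[parity == 1].groupby("animal_id", observed=True).size().items()}
    a_np = {str(k): int(v) for k, v in
            ppk[parity == 0].groupby("animal_id", observed=True).size().items()}

    # alcohol relapse: licks during the first daily bin
    r_start, r_end = resolve_window(relapse, "alcohol_relapse")
    relapse_w = relapse.schedule.occurrences("alcohol_relapse")[0]
    day1 = slice_interval(relapse, r_start, min(r_start + DAY_S, r_end))
    day1_licks = _reward_counts(day1, "lick")

    # motivation: replay the progressive-ratio state machine per animal
    mev = mot.events
    mpk = mev[(mev["kind"] == "nosepoke") & (mev["corner"] == "reward")]
    breakpoints: dict[str, int] = {}
    for aid, grp in mpk.groupby("animal_id", observed=True):
        breakpoints[str(aid)] = _breakpoint_replay(
            grp["timestamp_s"].to_numpy(), grp["visit_seq"].to_numpy(),
            ladder, cfg.breakpoint_mode)

    scored = {"motivation": mot, "extinction": ext, "cue_relapse": cue,
              "alcohol_relapse": relapse, "persistence": pers}
    present = {name: set(map(str, sl.events["animal_id"].unique()))
               for name, sl in scored.items()}

    completeness: dict[str, list[str]] = {}
    rows = []
    kept_ids = []
    for aid, weight in zip(log.registry["animal_id"],
                           log.registry["body_weight_g"]):
        aid = str(aid)
        missing = [name for name, ids in present.items() if aid not in ids]
        if missing:
            completeness[aid] = missing
            continue
        e = ext_np.get(aid, 0) / 7.0
        cr = float(cue_np.get(aid, 0))
        na = float(na_np.get(aid, 0))
        ar = compute_daily_consumption(
            day1_licks.get(aid, 0), lick_volume_ul,
            relapse_w.alcohol_fraction, float(weight))
        kept_ids.append(aid)
        rows.append({
            "animal_id": aid,
            "M": float(breakpoints.get(aid, ladder.steps[0])),
            "E": e, "E_delta": e - base_np.get(aid, 0),
            "CR": cr, "CR_delta": cr - last_np.get(aid, 0),
            "AR": ar,
            "P": na, "P_delta": na - a_np.get(aid, 0),
        })
    if completeness:
        warnings.warn(
            f"excluded {len(completeness)} animal(s) missing from scored "
            f"phases: {completeness}", CompletenessWarning, stacklevel=2,
        )

    alternates = pd.DataFrame(
        rows, columns=["animal_id", "M", "E", "E_delta", "CR", "CR_delta",
                       "AR", "P", "P_delta"])
    variant_cols = {
        "M": "M",
        "E": {"avg": "E", "delta": "E_delta"}[cfg.e_variant],
        "CR": {"daily": "CR", "delta": "CR_delta"}[cfg.cr_variant],
        "AR": "AR",
        "P": {"na": "P", "delta": "P_delta"}[cfg.p_variant],
    }
    values = (alternates[[variant_cols[b] for b in BEHAVIOR_NAMES]]
              .to_numpy(float) if len(rows) else np.empty((0, 5)))
    return BehaviorMatrix(animal_ids=kept_ids, values=values,
                          alternates=alternates, completeness=completeness)
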