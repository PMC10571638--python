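"""Domain model for IntelliCage-style behavioral event logs.

An IntelliCage records, per transponder-tagged mouse, every corner *visit*,
every *nosepoke* at the doors guarding the drinking bottles, and every *lick*
at a bottle nozzle.  This module defines a documented CSV dialect for such
logs, an in-memory container (:class:`EventLog`), the experiment phase
schedule (:class:`PhaseSchedule`), and validation of the structural
invariants the downstream behavioral indices rely on:

* visit_start / visit_end events for one ``(animal_id, visit_seq)`` pair are
  properly nested and visits of one animal never overlap in time;
* every nosepoke and lick carries the ``visit_seq`` of an enclosing visit of
  the same animal at the same corner (orphans are hard errors — the indices
  are counts, and silently dropping events would bias them);
* all timestamps are seconds since experiment start, with time zero anchored
  at the dark-phase onset of day 0 so that "daily" bins are 24-h bins.

Events exactly on a phase-window boundary belong to the *later* window
(half-open ``[start_s, end_s)`` intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ParseError,
    PhaseLookupError,
    ScheduleError,
    ValidationError,
)

DAY_S = 86400.0
"""Length of one daily bin, in seconds."""

CORNERS = ("reward", "water", "inactive")
SIDES = ("left", "right", "none")
KINDS = ("visit_start", "nosepoke", "lick", "visit_end")

#: Canonical within-timestamp ordering of event kinds.
KIND_ORDER = {"visit_start": 0, "nosepoke": 1, "lick": 2, "visit_end": 3}

EVENT_COLUMNS = ["animal_id", "timestamp_s", "corner", "side", "kind", "visit_seq"]
REGISTRY_COLUMNS = ["animal_id", "body_weight_g", "cohort"]
SCHEDULE_COLUMNS = ["phase", "occurrence", "start_s", "end_s", "alcohol_fraction", "reward_corner"]

PHASES = (
    "adaptation",
    "initiation_4",
    "initiation_8",
    "initiation_12",
    "free_access",
    "motivation",
    "extinction",
    "cue_relapse",
    "alcohol_relapse",
    "persistence",
)

#: Phases whose window duration is fixed by the protocol (seconds).
_FIXED_PHASE_SPANS = {"extinction": 7 * DAY_S, "persistence": 3 * DAY_S}
_SPAN_TOL_S = 1.0


@dataclass(frozen=True)
class PhaseWindow:
    """One contiguous experiment phase: ``[start_s, end_s)``."""

    phase: str
    start_s: float
    end_s: float
    alcohol_fraction: float = 0.0
    reward_corner: str = "reward"

    @property
    def span_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: np.ndarray | float) -> np.ndarray | bool:
        return (np.asarray(t) >= self.start_s) & (np.asarray(t) < self.end_s)


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered, non-overlapping phase windows covering the experiment.

    Occurrences of a recurring phase (e.g. two extinction tests) are numbered
    1, 2, ... in chronological order.
    """

    windows: tuple[PhaseWindow, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "windows", tuple(sorted(self.windows, key=lambda w: w.start_s))
        )

    def validate(self) -> "PhaseSchedule":
        for w in self.windows:
            if w.phase not in PHASES:
                raise ScheduleError(f"unknown phase {w.phase!r}")
            if not w.end_s > w.start_s:
                raise ScheduleError(f"window {w.phase}: end_s must exceed start_s")
            if not 0.0 <= w.alcohol_fraction <= 1.0:
                raise ScheduleError(f"window {w.phase}: alcohol_fraction outside [0, 1]")
            fixed = _FIXED_PHASE_SPANS.get(w.phase)
            if fixed is not None and abs(w.span_s - fixed) > _SPAN_TOL_S:
                raise ScheduleError(
                    f"{w.phase} window must span {fixed / DAY_S:g} days, got "
                    f"{w.span_s / DAY_S:g}"
                )
        for a, b in zip(self.windows, self.windows[1:]):
            if b.start_s < a.end_s:
                raise ScheduleError(
                    f"windows {a.phase} and {b.phase} overlap in time"
                )
        return self

    def occurrences(self, phase: str) -> list[PhaseWindow]:
        return [w for w in self.windows if w.phase == phase]

    def window(self, phase: str, occurrence: int = 1) -> PhaseWindow:
        occ = self.occurrences(phase)
        if not 1 <= occurrence <= len(occ):
            raise PhaseLookupError(
                f"phase {phase!r} occurrence {occurrence} not in schedule "
                f"({len(occ)} occurrence(s) present)"
            )
        return occ[occurrence - 1]

    def to_frame(self) -> pd.DataFrame:
        counts: dict[str, int] = {}
        rows = []
        for w in self.windows:
            counts[w.phase] = counts.get(w.phase, 0) + 1
            rows.append(
                {
                    "phase": w.phase,
                    "occurrence": counts[w.phase],
                    "start_s": w.start_s,
                    "end_s": w.end_s,
                    "alcohol_fraction": w.alcohol_fraction,
                    "reward_corner": w.reward_corner,
                }
            )
        return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhaseSchedule":
        windows = [
            PhaseWindow(
                phase=str(r.phase),
                start_s=float(r.start_s),
                end_s=float(r.end_s),
                alcohol_fraction=float(r.alcohol_fraction),
                reward_corner=str(r.reward_corner),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(tuple(windows)).validate()


@dataclass
class EventLog:
    """Events plus the animal registry and phase schedule they refer to.

    ``clip`` records, for slices produced by :func:`slice_phase` /
    :func:`slice_interval`, the half-open time interval the slice covers;
    it is ``None`` for a full log and is not persisted to disk.
    """

    events: pd.DataFrame
    registry: pd.DataFrame
    schedule: PhaseSchedule
    clip: tuple[float, float] | None = None

    # ------------------------------------------------------------------ #

    @property
    def animal_ids(self) -> list[str]:
        return list(self.registry["animal_id"])

    @property
    def n_events(self) -> int:
        return len(self.events)

    def canonical_sort(self) -> "EventLog":
        """Stable sort by (animal_id, timestamp, fixed kind order)."""
        ev = self.events
        if len(ev) == 0:
            return self
        rank = ev["kind"].map(KIND_ORDER).to_numpy()
        aid = ev["animal_id"]
        if isinstance(aid.dtype, pd.CategoricalDtype) and \
                aid.cat.categories.is_monotonic_increasing:
            a_key = aid.cat.codes.to_numpy()
        else:
            a_key = aid.to_numpy()
        order = np.lexsort((rank, ev["timestamp_s"].to_numpy(), a_key))
        return replace(self, events=ev.iloc[order].reset_index(drop=True))

    def for_animal(self, animal_id: str) -> pd.DataFrame:
        return self.events[self.events["animal_id"] == animal_id]

    # ------------------------------------------------------------------ #

    def validate(self) -> "EventLog":
        """Check every structural invariant; raise ValidationError on the
        first violated class, listing (up to 10) offending rows."""
        self.schedule.validate()
        reg = self.registry
        if reg["animal_id"].duplicated().any():
            dups = reg.loc[reg["animal_id"].duplicated(), "animal_id"].tolist()
            raise ValidationError(f"duplicate animal_id in registry: {dups[:10]}")
        if (reg["body_weight_g"] <= 0).any():
            bad = reg.loc[reg["body_weight_g"] <= 0, "animal_id"].tolist()
            raise ValidationError(f"non-positive body weight for: {bad[:10]}")

        ev = self.events
        missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise ValidationError(f"events missing columns: {missing}")
        if len(ev) == 0:
            return self

        for col, allowed in (("corner", CORNERS), ("side", SIDES), ("kind", KINDS)):
            bad = ~ev[col].isin(allowed)
            if bad.any():
                vals = sorted(ev.loc[bad, col].unique().tolist())
                raise ValidationError(f"invalid {col} value(s): {vals[:10]}")
        if (ev["timestamp_s"] < 0).any():
            raise ValidationError("negative timestamps present")

        known = set(reg["animal_id"])
        unknown = ~ev["animal_id"].isin(known)
        if unknown.any():
            ids = sorted(ev.loc[unknown, "animal_id"].unique().tolist())
            raise ValidationError(f"events reference unknown animal_id(s): {ids[:10]}")

        # integer key (animal, visit_seq) -> flat int64, for fast matching
        acode, acats = pd.factorize(ev["animal_id"], sort=True)
        seq = ev["visit_seq"].to_numpy(np.int64)
        if (seq < 0).any():
            raise ValidationError("negative visit_seq present")
        stride = int(seq.max()) + 1
        key = acode.astype(np.int64) * stride + seq
        t = ev["timestamp_s"].to_numpy(float)
        kind_arr = ev["kind"].to_numpy()
        corner_code = pd.factorize(ev["corner"], sort=True)[0]

        def _pairs(flat_keys):
            out = []
            for fk in flat_keys[:10]:
                out.append((str(acats[int(fk) // stride]), int(fk) % stride))
            return out

        is_start = kind_arr == "visit_start"
        is_end = kind_arr == "visit_end"
        for mask, what in ((is_start, "visit_start"), (is_end, "visit_end")):
            uniq, counts = np.unique(key[mask], return_counts=True)
            if (counts > 1).any():
                raise ValidationError(
                    f"duplicated {what} for visit(s): {_pairs(uniq[counts > 1])}"
                )
        sk, ek = key[is_start], key[is_end]
        if len(sk) != len(ek) or not np.array_equal(np.sort(sk), np.sort(ek)):
            odd = np.setxor1d(sk, ek)
            raise ValidationError(f"unpaired visit boundaries: {_pairs(odd)}")

        so = np.argsort(sk)
        vk, vt0 = sk[so], t[is_start][so]
        vc = corner_code[is_start][so]
        eo = np.argsort(ek)
        vt1 = t[is_end][eo]
        inverted = vt1 < vt0
        if inverted.any():
            raise ValidationError(
                f"visit ends before it starts: {_pairs(vk[inverted])}")

        order = np.lexsort((vt0, vk // stride))
        same = (vk // stride)[order][1:] == (vk // stride)[order][:-1]
        overlap = same & (vt0[order][1:] < vt1[order][:-1])
        if overlap.any():
            raise ValidationError(
                "overlapping visits for one animal: "
                f"{_pairs(vk[order][1:][overlap])}"
            )

        inner = (kind_arr == "nosepoke") | (kind_arr == "lick")
        if inner.any():
            ik, it, ic = key[inner], t[inner], corner_code[inner]
            if len(vk) == 0:
                raise ValidationError(
                    "orphan nosepoke/lick events (log contains no visits): "
                    f"{_pairs(ik)}"
                )
            pos = np.searchsorted(vk, ik)
            pos_c = np.clip(pos, 0, len(vk) - 1)
            orphan = (
                (pos >= len(vk)) | (vk[pos_c] != ik)
                | (it < vt0[pos_c]) | (it > vt1[pos_c]) | (ic != vc[pos_c])
            )
            if orphan.any():
                raise ValidationError(
                    "orphan nosepoke/lick events (no enclosing visit of the "
                    f"same animal and corner): {_pairs(ik[orphan])}"
                )
        return self


# ---------------------------------------------------------------------- #
# IO
# ---------------------------------------------------------------------- #

def _read_csv(path, columns, converters):
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing column(s) {missing}", line=1)
    out = {}
    for col in columns:
        conv = converters.get(col, str)
        if conv is str:
            out[col] = df[col].astype(str)
            continue
        try:
            out[col] = conv(df[col])
        except (ValueError, TypeError):
            for i, raw in enumerate(df[col]):
                try:
                    conv(pd.Series([raw]))
                except (ValueError, TypeError):
                    raise ParseError(
                        f"{path.name}: cannot parse {col}={raw!r}", line=i + 2
                    ) from None
            raise
    return pd.DataFrame(out, columns=columns)


def _to_float(s: pd.Series) -> pd.Series:
    return s.astype(np.float64)


def _to_int(s: pd.Series) -> pd.Series:
    return s.astype(np.int64)


def read_event_log(path, schedule_path, registry_path) -> EventLog:
    """Read the events/schedule/registry CSV triple into a validated,
    canonically sorted :class:`EventLog`."""
    events = _read_csv(
        path, EVENT_COLUMNS, {"timestamp_s": _to_float, "visit_seq": _to_int}
    )
    registry = _read_csv(registry_path, REGISTRY_COLUMNS, {"body_weight_g": _to_float})
    sched_df = _read_csv(
        schedule_path, SCHEDULE_COLUMNS,
        {"occurrence": _to_int, "start_s": _to_float, "end_s": _to_float,
         "alcohol_fraction": _to_float},
    )
    schedule = PhaseSchedule.from_frame(sched_df)
    log = EventLog(events=events, registry=registry, schedule=schedule)
    return log.canonical_sort().validate()


def write_event_log(log: EventLog, path, schedule_path, registry_path) -> None:
    """Write the CSV triple; ``read_event_log`` round-trips it exactly."""
    log.events[EVENT_COLUMNS].to_csv(path, index=False)
    log.registry[REGISTRY_COLUMNS].to_csv(registry_path, index=False)
    log.schedule.to_frame().to_csv(schedule_path, index=False)


# ---------------------------------------------------------------------- #
# Slicing
# ---------------------------------------------------------------------- #

def slice_interval(log: EventLog, start_s: float, end_s: float) -> EventLog:
    """Events with ``start_s <= t < end_s``; schedule left untouched."""
    t = log.events["timestamp_s"]
    ev = log.events[(t >= start_s) & (t < end_s)].reset_index(drop=True)
    return replace(log, events=ev, clip=(float(start_s), float(end_s)))


def slice_phase(log: EventLog, phase: str, occurrence: int = 1) -> EventLog:
    """Restrict the log to one occurrence of a phase.

    The returned log's schedule contains only that window, and ``clip``
    records the window's half-open interval.
    """
    w = log.schedule.window(phase, occurrence)
    sliced = slice_interval(log, w.start_s, w.end_s)
    return replace(sliced, schedule=PhaseSchedule((w,)))


def resolve_window(log: EventLog, phase: str | None = None) -> tuple[float, float]:
    """The time interval a slice covers: its ``clip`` if set, else the single
    window of ``phase`` in its schedule."""
    if log.clip is not None:
        return log.clip
    if phase is not None:
        occ = log.schedule.occurrences(phase)
        if len(occ) != 1:
            raise ScheduleError(
                f"log has {len(occ)} {phase!r} windows; slice the log to one "
                "occurrence first"
            )
        return (occ[0].start_s, occ[0].end_s)
    raise ScheduleError("cannot resolve the time window of an unsliced log")
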