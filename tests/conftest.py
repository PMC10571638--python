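from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from audpipe import (
    DAY_S,
    EventLog,
    PhaseSchedule,
    PhaseWindow,
    default_config,
    simulate_cohort,
)
from audpipe.event_model import EVENT_COLUMNS


def make_registry(animal_ids, weight=25.0):
    return pd.DataFrame({
        "animal_id": list(animal_ids),
        "body_weight_g": [weight] * len(animal_ids),
        "cohort": ["test"] * len(animal_ids),
    })


def make_events(rows):
    """rows: (animal_id, timestamp_s, corner, side, kind, visit_seq)."""
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def visit_rows(animal, corner, start, end, seq, poke_times=(), lick_times=(),
               side="left"):
    """One visit plus its inner events, as event rows."""
    rows = [(animal, start, corner, "none", "visit_start", seq)]
    rows += [(animal, t, corner, side, "nosepoke", seq) for t in poke_times]
    rows += [(animal, t, corner, side, "lick", seq) for t in lick_times]
    rows.append((animal, end, corner, "none", "visit_end", seq))
    return rows


def poke_log(animal_ids, schedule, pokes_by_animal):
    """A validated log whose reward-corner nosepokes are given per animal as
    a list of (timestamp, visit_seq); each poke gets its own enclosing visit
    unless consecutive pokes share a visit_seq."""
    rows = []
    for aid in animal_ids:
        pokes = pokes_by_animal.get(aid, [])
        by_visit: dict[int, list[float]] = {}
        for t, seq in pokes:
            by_visit.setdefault(seq, []).append(t)
        for seq, times in by_visit.items():
            times = sorted(times)
            rows += visit_rows(aid, "reward", times[0] - 0.5, times[-1] + 0.5,
                               seq, poke_times=times)
    log = EventLog(events=make_events(rows), registry=make_registry(animal_ids),
                   schedule=schedule)
    return log.canonical_sort().validate()


def single_window_schedule(phase, start_days, end_days, alcohol_fraction=0.10):
    return PhaseSchedule((PhaseWindow(phase, start_days * DAY_S,
                                      end_days * DAY_S, alcohol_fraction),))


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort reused across tests (deterministic)."""
    return simulate_cohort(default_config(12, 321))


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    from audpipe import build_behavior_matrix

    log, _truth = small_cohort
    return build_behavior_matrix(log)
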