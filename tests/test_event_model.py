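import numpy as np
import pandas as pd
import pytest

from audpipe import (
    DAY_S,
    EventLog,
    PhaseSchedule,
    PhaseWindow,
    default_config,
    read_event_log,
    simulate_cohort,
    slice_phase,
    write_event_log,
)
from audpipe.errors import (
    ParseError,
    PhaseLookupError,
    ScheduleError,
    ValidationError,
)

from conftest import make_events, make_registry, single_window_schedule, visit_rows


@pytest.fixture()
def two_phase_schedule():
    return PhaseSchedule((
        PhaseWindow("free_access", 0.0, 2 * DAY_S, 0.10),
        PhaseWindow("extinction", 2 * DAY_S, 9 * DAY_S, 0.0),
        PhaseWindow("extinction", 10 * DAY_S, 17 * DAY_S, 0.0),
    ))


def test_minimal_log_roundtrip(tmp_path, two_phase_schedule):
    rows = visit_rows("A1", "reward", 10.0, 20.0, 1, poke_times=[12.0])
    log = EventLog(make_events(rows), make_registry(["A1"]), two_phase_schedule)
    log.validate()
    write_event_log(log, tmp_path / "e.csv", tmp_path / "s.csv", tmp_path / "r.csv")
    back = read_event_log(tmp_path / "e.csv", tmp_path / "s.csv", tmp_path / "r.csv")
    assert back.n_events == 3
    pd.testing.assert_frame_equal(
        back.events, log.canonical_sort().events, check_dtype=False)
    assert back.schedule == two_phase_schedule
    assert list(back.registry["animal_id"]) == ["A1"]


def test_empty_events_file_is_valid(tmp_path, two_phase_schedule):
    log = EventLog(make_events([]), make_registry(["A1"]), two_phase_schedule)
    write_event_log(log, tmp_path / "e.csv", tmp_path / "s.csv", tmp_path / "r.csv")
    back = read_event_log(tmp_path / "e.csv", tmp_path / "s.csv", tmp_path / "r.csv")
    assert back.n_events == 0


def test_simulator_output_roundtrips(tmp_path):
    log, _ = simulate_cohort(default_config(3, 11))
    write_event_log(log, tmp_path / "e.csv", tmp_path / "s.csv", tmp_path / "r.csv")
    back = read_event_log(tmp_path / "e.csv", tmp_path / "s.csv", tmp_path / "r.csv")
    assert back.n_events == log.n_events
    np.testing.assert_array_equal(back.events["timestamp_s"].to_numpy(),
                                  log.events["timestamp_s"].to_numpy())
    assert (back.events["kind"].to_numpy().astype(str)
            == log.events["kind"].to_numpy().astype(str)).all()


def test_canonical_sort_is_idempotent():
    log, _ = simulate_cohort(default_config(3, 5))
    once = log.canonical_sort()
    twice = once.canonical_sort()
    pd.testing.assert_frame_equal(once.events, twice.events)


def test_malformed_row_names_line(tmp_path, two_phase_schedule):
    log = EventLog(make_events([]), make_registry(["A1"]), two_phase_schedule)
    write_event_log(log, tmp_path / "e.csv", tmp_path / "s.csv", tmp_path / "r.csv")
    (tmp_path / "e.csv").write_text(
        "animal_id,timestamp_s,corner,side,kind,visit_seq\n"
        "A1,10.0,reward,none,visit_start,1\n"
        "A1,not_a_number,reward,left,nosepoke,1\n"
    )
    with pytest.raises(ParseError, match="line 3"):
        read_event_log(tmp_path / "e.csv", tmp_path / "s.csv", tmp_path / "r.csv")


@pytest.mark.parametrize("mutation, message", [
    ("orphan", "orphan"),
    ("unknown_animal", "unknown animal_id"),
    ("unpaired", "unpaired"),
    ("overlap", "overlapping"),
    ("wrong_corner", "orphan"),
])
def test_validation_rejects_malformed_logs(two_phase_schedule, mutation, message):
    rows = visit_rows("A1", "reward", 10.0, 20.0, 1, poke_times=[12.0])
    rows += visit_rows("A1", "water", 30.0, 40.0, 2)
    if mutation == "orphan":
        rows.append(("A1", 55.0, "reward", "left", "lick", 9))
    elif mutation == "unknown_animal":
        rows += visit_rows("GHOST", "water", 50.0, 60.0, 1)
    elif mutation == "unpaired":
        rows.append(("A1", 70.0, "reward", "none", "visit_start", 3))
    elif mutation == "overlap":
        rows += visit_rows("A1", "water", 35.0, 45.0, 3)
    elif mutation == "wrong_corner":
        rows.append(("A1", 15.0, "water", "left", "nosepoke", 1))
    log = EventLog(make_events(rows), make_registry(["A1"]), two_phase_schedule)
    with pytest.raises(ValidationError, match=message):
        log.validate()


def test_schedule_rejects_overlapping_and_misshapen_windows():
    with pytest.raises(ScheduleError, match="overlap"):
        PhaseSchedule((
            PhaseWindow("free_access", 0.0, 2 * DAY_S),
            PhaseWindow("motivation", 1 * DAY_S, 3 * DAY_S),
        )).validate()
    with pytest.raises(ScheduleError, match="7 days"):
        single_window_schedule("extinction", 0, 3, 0.0).validate()
    with pytest.raises(ScheduleError, match="3 days"):
        single_window_schedule("persistence", 0, 4).validate()


def test_slice_phase_selects_requested_occurrence(two_phase_schedule):
    rows = []
    seq = 1
    for day in (1, 4, 12):  # free access, first extinction, second extinction
        t = day * DAY_S + 100.0
        rows += visit_rows("A1", "reward", t, t + 10.0, seq, poke_times=[t + 1])
        seq += 1
    log = EventLog(make_events(rows), make_registry(["A1"]), two_phase_schedule)
    log = log.canonical_sort().validate()

    second = slice_phase(log, "extinction", 2)
    assert second.n_events == 3
    assert (second.events["timestamp_s"] >= 10 * DAY_S).all()
    with pytest.raises(PhaseLookupError):
        slice_phase(log, "extinction", 3)
    with pytest.raises(PhaseLookupError):
        slice_phase(log, "motivation", 1)


def test_slice_on_empty_window_returns_empty_log(two_phase_schedule):
    log = EventLog(make_events([]), make_registry(["A1"]), two_phase_schedule)
    assert slice_phase(log, "extinction", 1).n_events == 0


def test_boundary_events_belong_to_later_window(two_phase_schedule):
    # a visit starting exactly at the extinction boundary is extinction's
    t0 = 2 * DAY_S
    rows = visit_rows("A1", "reward", t0, t0 + 5.0, 1)
    log = EventLog(make_events(rows), make_registry(["A1"]), two_phase_schedule)
    log = log.canonical_sort().validate()
    assert slice_phase(log, "free_access", 1).n_events == 0
    assert slice_phase(log, "extinction", 1).n_events == 2


def test_phase_slices_partition_the_log():
    log, _ = simulate_cohort(default_config(4, 17))
    seen = 0
    keys = set()
    for w in log.schedule.windows:
        occ = sum(1 for v in log.schedule.windows
                  if v.phase == w.phase and v.start_s <= w.start_s)
        sl = slice_phase(log, w.phase, occ)
        seen += sl.n_events
        k = set(zip(sl.events["animal_id"].astype(str),
                    sl.events["timestamp_s"], sl.events["kind"].astype(str)))
        assert not (keys & k), "an event appeared in two phase slices"
        keys |= k
    assert seen == log.n_events  # simulator places every event in a window
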