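import numpy as np
import pandas as pd
import pytest

from audpipe import (
    DAY_S,
    EventLog,
    RatioLadder,
    build_behavior_matrix,
    calibrate_lick_volume,
    compute_breakpoint,
    compute_cue_relapse_index,
    compute_daily_consumption,
    compute_extinction_index,
    compute_persistence_index,
    default_config,
    simulate_cohort,
    slice_interval,
    slice_phase,
)
from audpipe.behavioral_indices import DEFAULT_LICK_VOLUME_UL
from audpipe.errors import AnimalLookupError, ConfigError, DomainError, ScheduleError

from conftest import poke_log, single_window_schedule
from oracles import brute_force_breakpoint, random_poke_stream

MOTIVATION = single_window_schedule("motivation", 0, 3)


def stream_log(times, visits, animal="A1"):
    return poke_log([animal], MOTIVATION,
                    {animal: list(zip(times, visits))})


# --------------------------------------------------------------------- #
# breakpoint
# --------------------------------------------------------------------- #

def test_breakpoint_no_pokes_returns_first_requirement():
    log = poke_log(["A1"], MOTIVATION, {})
    assert compute_breakpoint(log, "A1") == 2


def test_breakpoint_ten_sets_of_two_advances_to_four():
    # 10 bursts of 2 pokes (gap 0.5 s), each in its own visit
    times, visits = [], []
    t = 100.0
    for v in range(1, 11):
        times += [t, t + 0.5]
        visits += [v, v]
        t += 60.0
    assert compute_breakpoint(stream_log(times, visits), "A1") == 4


def test_breakpoint_nine_sets_do_not_advance():
    times, visits = [], []
    t = 100.0
    for v in range(1, 10):
        times += [t, t + 0.5]
        visits += [v, v]
        t += 60.0
    assert compute_breakpoint(stream_log(times, visits), "A1") == 2


def test_breakpoint_gap_resets_partial_burst():
    # 2-poke requirement, but a >= 1 s gap splits the pair: no set completed
    times = [100.0, 101.5]
    visits = [1, 1]
    log = stream_log(times, visits)
    assert compute_breakpoint(log, "A1", mode="last_completed") == 2
    # with a < 1 s gap the pair completes one set
    log2 = stream_log([100.0, 100.5], [1, 1])
    assert compute_breakpoint(log2, "A1") == 2  # requirement unchanged


def test_breakpoint_matches_brute_force_oracle_on_random_streams():
    rng = np.random.default_rng(2024)
    ladder = RatioLadder()
    for _ in range(500):
        t, v = random_poke_stream(rng)
        if len(t) == 0:
            continue
        log = stream_log(t, v)
        got = compute_breakpoint(log, "A1", ladder)
        want = brute_force_breakpoint(t, v, ladder.steps)
        assert got == want
        got_lc = compute_breakpoint(log, "A1", ladder, mode="last_completed")
        want_lc = brute_force_breakpoint(t, v, ladder.steps,
                                         mode="last_completed")
        assert got_lc == want_lc


def test_breakpoint_monotone_under_appended_sets():
    """Appending further completed sets never lowers the FR level."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        t, v = random_poke_stream(rng, max_visits=10)
        base = compute_breakpoint(stream_log(t, v), "A1") if len(t) else 2
        # append 10 clean 36-poke bursts in fresh visits
        t2, v2 = list(t), list(v)
        t0 = (t[-1] if len(t) else 0.0) + 100.0
        vmax = (int(max(v)) if len(v) else 0) + 1
        for b in range(10):
            for i in range(36):
                t2.append(t0 + b * 60.0 + i * 0.4)
                v2.append(vmax + b)
        extended = compute_breakpoint(stream_log(t2, v2), "A1")
        assert extended >= base


def test_breakpoint_errors():
    log = poke_log(["A1"], MOTIVATION, {})
    with pytest.raises(AnimalLookupError):
        compute_breakpoint(log, "NOPE")
    with pytest.raises(ConfigError):
        compute_breakpoint(log, "A1", RatioLadder(steps=()))
    with pytest.raises(ConfigError):
        compute_breakpoint(log, "A1", mode="whatever")


# --------------------------------------------------------------------- #
# extinction / cue relapse
# --------------------------------------------------------------------- #

def _extinction_fixture(daily_counts, baseline_count):
    sched = single_window_schedule("extinction", 1, 8, 0.0)
    pokes = []
    seq = 1
    for t in np.linspace(0.25 * DAY_S, 0.75 * DAY_S, baseline_count):
        pokes.append((float(t), seq))
        seq += 1
    for day, n in enumerate(daily_counts):
        for t in np.linspace(0.2 * DAY_S, 0.8 * DAY_S, n):
            pokes.append((float((1 + day) * DAY_S + t), seq))
            seq += 1
    log = poke_log(["A1"], sched, {"A1": pokes})
    ext = slice_phase(log, "extinction", 1)
    baseline = slice_interval(log, 0.0, DAY_S)
    return ext, baseline


def test_extinction_index_hand_arithmetic():
    ext, baseline = _extinction_fixture([14, 10, 7, 7, 7, 7, 7], 20)
    avg, delta = compute_extinction_index(ext, baseline, "A1")
    assert avg == pytest.approx(59 / 7)
    assert round(avg, 2) == 8.43
    assert round(delta, 2) == -11.57


def test_extinction_zero_everywhere():
    ext, baseline = _extinction_fixture([0] * 7, 0)
    assert compute_extinction_index(ext, baseline, "A1") == (0.0, 0.0)


def test_extinction_average_invariant_to_day_permutation():
    a, _ = compute_extinction_index(*_extinction_fixture([14, 10, 7, 7, 7, 7, 7], 0),
                                    animal_id="A1")
    b, _ = compute_extinction_index(*_extinction_fixture([7, 7, 7, 14, 7, 10, 7], 0),
                                    animal_id="A1")
    assert a == b


def test_extinction_wrong_span_raises():
    sched = single_window_schedule("extinction", 1, 8, 0.0)
    log = poke_log(["A1"], sched, {})
    bad = slice_interval(log, DAY_S, 4 * DAY_S)  # 3-day slice
    baseline = slice_interval(log, 0.0, DAY_S)
    with pytest.raises(ScheduleError, match="7 daily"):
        compute_extinction_index(bad, baseline, "A1")


def test_cue_relapse_hand_arithmetic():
    sched = single_window_schedule("cue_relapse", 1, 2, 0.0)
    pokes = [(float(30 + i), 1 + i) for i in range(30)]  # last ext day
    pokes += [(float(DAY_S + 40 + i * 10), 100 + i) for i in range(120)]
    log = poke_log(["A1"], sched, {"A1": pokes})
    cue = slice_phase(log, "cue_relapse", 1)
    last_day = slice_interval(log, 0.0, DAY_S)
    daily, delta = compute_cue_relapse_index(cue, last_day, "A1")
    assert (daily, delta) == (120.0, 90.0)
    assert delta + 30 == daily  # algebraic identity


def test_cue_relapse_zero_pokes():
    sched = single_window_schedule("cue_relapse", 1, 2, 0.0)
    pokes = [(float(30 + i), 1 + i) for i in range(15)]
    log = poke_log(["A1"], sched, {"A1": pokes})
    daily, delta = compute_cue_relapse_index(
        slice_phase(log, "cue_relapse", 1), slice_interval(log, 0.0, DAY_S), "A1")
    assert (daily, delta) == (0.0, -15.0)


# --------------------------------------------------------------------- #
# lick volume / consumption
# --------------------------------------------------------------------- #

def test_lick_volume_calibration():
    assert calibrate_lick_volume(9700.0, 5000) == pytest.approx(1.94)
    assert calibrate_lick_volume(0.0, 100) == 0.0
    assert DEFAULT_LICK_VOLUME_UL == 1.94
    with pytest.raises(ZeroDivisionError, match="n_licks"):
        calibrate_lick_volume(100.0, 0)


def test_daily_consumption_formula():
    assert compute_daily_consumption(1000, 1.94, 0.12, 20.0) == pytest.approx(11.64)
    assert compute_daily_consumption(0, 1.94, 0.12, 20.0) == 0.0
    # joint linearity / inverse weight scaling
    base = compute_daily_consumption(500, 1.94, 0.10, 25.0)
    assert compute_daily_consumption(1000, 1.94, 0.10, 25.0) == pytest.approx(2 * base)
    assert compute_daily_consumption(500, 3.88, 0.10, 25.0) == pytest.approx(2 * base)
    assert compute_daily_consumption(500, 1.94, 0.20, 25.0) == pytest.approx(2 * base)
    assert compute_daily_consumption(500, 1.94, 0.10, 50.0) == pytest.approx(base / 2)
    with pytest.raises(DomainError):
        compute_daily_consumption(100, 1.94, 0.12, 0.0)


# --------------------------------------------------------------------- #
# persistence
# --------------------------------------------------------------------- #

def _persistence_log(na_counts, a_counts):
    sched = single_window_schedule("persistence", 0, 3)
    block = 3 * DAY_S / 12
    pokes = []
    seq = 1
    for i in range(12):
        counts = a_counts[i // 2] if i % 2 == 0 else na_counts[i // 2]
        for t in np.linspace(i * block + 60, (i + 1) * block - 60, counts):
            pokes.append((float(t), seq))
            seq += 1
    return poke_log(["A1"], sched, {"A1": pokes})


def test_persistence_hand_arithmetic():
    log = _persistence_log([5] * 6, [10] * 6)
    pers = slice_phase(log, "persistence", 1)
    assert compute_persistence_index(pers, "A1") == (30.0, -30.0)


def test_persistence_zero_and_antisymmetry():
    log = _persistence_log([0] * 6, [0] * 6)
    assert compute_persistence_index(slice_phase(log, "persistence", 1),
                                     "A1") == (0.0, 0.0)
    swapped = _persistence_log([10] * 6, [5] * 6)
    _, delta = compute_persistence_index(slice_phase(swapped, "persistence", 1),
                                         "A1")
    assert delta == 30.0  # swapping A and nA labels negates the difference


def test_persistence_wrong_span_raises():
    log = _persistence_log([1] * 6, [1] * 6)
    bad = slice_interval(log, 0.0, DAY_S)
    with pytest.raises(ScheduleError, match="3 daily"):
        compute_persistence_index(bad, "A1")


# --------------------------------------------------------------------- #
# counting indices ignore other corners
# --------------------------------------------------------------------- #

def test_indices_invariant_to_other_corner_events():
    ext, baseline = _extinction_fixture([3, 3, 3, 3, 3, 3, 3], 5)
    before = compute_extinction_index(ext, baseline, "A1")
    # inject water-corner activity into the extinction slice
    extra_rows = []
    from conftest import visit_rows
    for i in range(20):
        t = ext.clip[0] + 1000.0 + i * 500.0
        extra_rows += visit_rows("A1", "water", t, t + 5.0, 10_000 + i,
                                 poke_times=[t + 1.0], lick_times=[t + 2.0])
    noisy = EventLog(
        events=pd.concat([ext.events, pd.DataFrame(
            extra_rows, columns=ext.events.columns)], ignore_index=True),
        registry=ext.registry, schedule=ext.schedule, clip=ext.clip,
    ).canonical_sort()
    assert compute_extinction_index(noisy, baseline, "A1") == before


# --------------------------------------------------------------------- #
# matrix assembly
# --------------------------------------------------------------------- #

def test_behavior_matrix_from_simulator(small_cohort, small_matrix):
    log, _truth = small_cohort
    assert small_matrix.values.shape == (12, 5)
    assert not np.isnan(small_matrix.values).any()
    assert small_matrix.completeness == {}
    # column M equals per-animal breakpoint on the motivation slice
    mot = slice_phase(log, "motivation", 1)
    m_col = small_matrix.values[:, 0]
    for i, aid in enumerate(small_matrix.animal_ids):
        assert m_col[i] == compute_breakpoint(mot, aid)
    # alternates carry all variants
    assert list(small_matrix.alternates.columns) == [
        "animal_id", "M", "E", "E_delta", "CR", "CR_delta", "AR", "P", "P_delta"]


def test_behavior_matrix_single_animal():
    log, _ = simulate_cohort(default_config(1, 4))
    matrix = build_behavior_matrix(log)
    assert matrix.values.shape == (1, 5)
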