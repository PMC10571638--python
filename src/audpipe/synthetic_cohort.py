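"""Synthetic IntelliCage cohorts with a latent AUD-prone subpopulation.

The generator emulates the structure of a long home-cage alcohol protocol:
adaptation, alcohol initiation at increasing concentrations (4/8/12%), a long
free-access period (10%), a progressive-ratio motivation test, a 3-day
persistence test with alternating 6-h active/non-active periods, 7 days of
extinction, a 24-h cue relapse, and an alcohol relapse.

Each animal carries a latent class (``prone`` with probability
``prone_fraction``, else ``resistant``) and a 5-vector of latent traits —
propensities for motivation, extinction responding, cue reactivity, relapse
drinking, and persistence.  Traits are multivariate normal with an
*equicorrelated* covariance whose off-diagonal correlation differs by class
(``rho_prone`` vs ``rho_resistant``): the prone subpopulation's behaviors are
mutually correlated, the resistant subpopulation's are not.  Traits map to
non-negative event rates through a softplus link.

Reproducibility: one root seed spawns independent per-animal substreams via
``np.random.SeedSequence(seed, spawn_key=(1, i))`` (cohort-level draws use
``spawn_key=(0,)``), so output is byte-identical given the config and no
animal's stream depends on another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .event_model import (
    DAY_S,
    EventLog,
    PhaseSchedule,
    PhaseWindow,
    write_event_log,
)

TRAIT_NAMES = ("motivation", "extinction", "cue_reactivity", "relapse", "persistence")

_H12 = DAY_S / 2.0  # half-day block (dark or light), seconds


def softplus(x):
    """Positive link mapping latent traits to rates: log(1 + e^x)."""
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def equicorrelation(rho: float, p: int = 5) -> np.ndarray:
    """p x p correlation matrix with constant off-diagonal rho."""
    return np.full((p, p), rho) + (1.0 - rho) * np.eye(p)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the cohort generator.

    Trait means are on the latent (pre-softplus) scale; the default gap of
    2.0 between classes makes prone rates roughly three times resistant ones,
    a well-separated regime.  Event-rate parameters are deliberately modest
    so that a ~60-day log stays compact while preserving the trait-driven
    contrasts the behavioral indices measure.
    """

    n_animals: int
    seed: int
    prone_fraction: float = 0.38
    trait_mean_prone: tuple[float, ...] = (2.0, 2.0, 2.0, 2.0, 2.0)
    trait_mean_resistant: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    trait_sd: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    rho_prone: float = 0.6
    rho_resistant: float = 0.0
    # event-rate parameters
    visit_rate_per_h: float = 1.0          # total corner-visit rate (average)
    dark_light_ratio: float = 3.0          # nocturnal activity bias
    nosepokes_per_visit: float = 1.3
    licks_per_reward: float = 10.0         # licks per rewarded nosepoke
    licks_per_water_poke: float = 3.0
    extinction_level_scale: float = 30.0   # day-0 nosepokes/day per softplus unit
    extinction_decay_per_day: float = 0.5  # baseline decay; slower for high traits
    cue_scale: float = 40.0                # cue-day nosepokes per softplus unit
    relapse_licks_scale: float = 500.0     # relapse-day-1 licks per softplus unit
    persistence_scale: float = 60.0        # non-active nosepokes per softplus unit
    persistence_active_pokes: float = 80.0 # active-period nosepokes (trait-free)
    breakpoint_gain: float = 3.0           # ladder steps climbed per softplus unit
    body_weight_mean_g: float = 25.0
    body_weight_sd_g: float = 2.0

    def validate(self) -> "SimConfig":
        if self.n_animals < 0:
            raise ConfigError("n_animals must be >= 0")
        if not 0.0 <= self.prone_fraction <= 1.0:
            raise ConfigError("prone_fraction must lie in [0, 1]")
        for name, rho in (("rho_prone", self.rho_prone),
                          ("rho_resistant", self.rho_resistant)):
            if not -0.25 < rho < 1.0:
                raise ConfigError(
                    f"{name}={rho} gives a non-positive-definite 5x5 "
                    "equicorrelation matrix (need rho in (-1/4, 1))"
                )
        rates = (self.visit_rate_per_h, self.nosepokes_per_visit,
                 self.licks_per_reward, self.licks_per_water_poke,
                 self.extinction_level_scale, self.extinction_decay_per_day,
                 self.cue_scale, self.relapse_licks_scale,
                 self.persistence_scale, self.persistence_active_pokes)
        if any(r < 0 for r in rates):
            raise ConfigError("event-rate parameters must be >= 0")
        if any(s <= 0 for s in self.trait_sd):
            raise ConfigError("trait_sd entries must be > 0")
        if self.body_weight_mean_g <= 0:
            raise ConfigError("body_weight_mean_g must be > 0")
        return self


@dataclass
class LatentTruth:
    """Ground truth of a simulated cohort: one row per animal with its
    latent class and 5 latent traits (for parameter-recovery tests)."""

    table: pd.DataFrame  # animal_id, latent_class, trait_* columns

    COLUMNS = ["animal_id", "latent_class"] + [f"trait_{t}" for t in TRAIT_NAMES]

    def to_csv(self, path) -> None:
        self.table[self.COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LatentTruth":
        return cls(pd.read_csv(path, dtype={"animal_id": str}))


def default_config(n_animals: int, seed: int) -> SimConfig:
    """Cohort-sized defaults: 38% prone, correlated prone traits
    (rho = 0.6), uncorrelated resistant traits."""
    return SimConfig(n_animals=n_animals, seed=seed).validate()


def default_schedule() -> PhaseSchedule:
    """The protocol timeline used by the simulator (seconds from the day-0
    dark-phase onset): adaptation, 4/8/12% initiation, 35-day free access,
    motivation, persistence, 7-day extinction, 24-h cue relapse, relapse."""
    d = DAY_S
    layout = [
        ("adaptation", 0, 3, 0.0),
        ("initiation_4", 3, 6, 0.04),
        ("initiation_8", 6, 9, 0.08),
        ("initiation_12", 9, 12, 0.12),
        ("free_access", 12, 47, 0.10),
        ("motivation", 47, 50, 0.10),
        ("persistence", 50, 53, 0.10),
        ("extinction", 53, 60, 0.0),
        ("cue_relapse", 60, 61, 0.0),
        ("alcohol_relapse", 61, 63, 0.10),
    ]
    windows = tuple(
        PhaseWindow(phase=p, start_s=a * d, end_s=b * d, alcohol_fraction=f)
        for p, a, b, f in layout
    )
    return PhaseSchedule(windows).validate()


# ---------------------------------------------------------------------- #
# per-animal event generation
# ---------------------------------------------------------------------- #

#: integer codes used internally by the generator (decoded to pandas
#: Categorical columns at assembly time)
_CORNER_CATS = ("inactive", "reward", "water")   # lexicographic
_SIDE_CATS = ("left", "none", "right")
_KIND_CATS = ("visit_start", "nosepoke", "lick", "visit_end")  # canonical order
_REWARD, _WATER = 1, 2
_LEFT, _NONE, _RIGHT = 0, 1, 2


class _Intents:
    """Accumulator of visit 'intents' (start, dur, corner code, pokes, licks)."""

    def __init__(self):
        self.start, self.dur, self.corner = [], [], []
        self.pokes, self.licks = [], []

    def add(self, start, dur, corner_code, pokes, licks):
        n = len(start)
        if n == 0:
            return
        self.start.append(np.asarray(start, float))
        self.dur.append(np.asarray(dur, float))
        self.corner.append(np.full(n, corner_code, dtype=np.uint8))
        self.pokes.append(np.asarray(pokes, np.int64))
        self.licks.append(np.asarray(licks, np.int64))

    def arrays(self):
        if not self.start:
            z = np.empty(0)
            i = np.empty(0, np.int64)
            return z, z, np.empty(0, np.uint8), i, i
        return (np.concatenate(self.start), np.concatenate(self.dur),
                np.concatenate(self.corner), np.concatenate(self.pokes),
                np.concatenate(self.licks))


def _block_arrival_times(rng, t0, t1, rate_per_h, ratio):
    """Poisson arrivals in [t0, t1) with piecewise-constant dark/light rates.

    Day 0 starts at the dark-phase onset, so even 12-h blocks are dark.
    Dark and light rates average to ``rate_per_h`` with dark:light ``ratio``.
    """
    if t1 <= t0 or rate_per_h <= 0:
        return np.empty(0)
    edges = np.arange(np.floor(t0 / _H12) * _H12, t1 + _H12, _H12)
    lo = np.clip(edges[:-1], t0, t1)
    hi = np.clip(edges[1:], t0, t1)
    dark = (np.floor(edges[:-1] / _H12).astype(np.int64) % 2) == 0
    mult = np.where(dark, 2 * ratio / (ratio + 1), 2 / (ratio + 1))
    lam = rate_per_h * mult * (hi - lo) / 3600.0
    counts = rng.poisson(np.maximum(lam, 0.0))
    t = np.repeat(lo, counts) + rng.random(int(counts.sum())) * np.repeat(hi - lo, counts)
    return np.sort(t)


def _background_visits(rng, cfg, intents, t0, t1, corner_code, licks_per_poke):
    """Free-running drinking/exploration visits at half the total visit rate."""
    starts = _block_arrival_times(rng, t0, t1 - 60.0, cfg.visit_rate_per_h * 0.5,
                                  cfg.dark_light_ratio)
    n = len(starts)
    if n == 0:
        return
    durs = rng.exponential(20.0, n) + 2.0
    durs = np.minimum(durs, t1 - starts - 1e-3)
    pokes = rng.poisson(cfg.nosepokes_per_visit, n)
    licks = rng.poisson(licks_per_poke * pokes)
    licks[pokes == 0] = 0
    intents.add(starts, durs, corner_code, pokes, licks)


def _count_driven_visits(rng, intents, t0, t1, corner_code, total_pokes,
                         licks_per_poke=0.0, pokes_per_visit=2.5):
    """Place a given total number of reward-corner nosepokes into visits with
    uniform start times in [t0, t1)."""
    if total_pokes <= 0:
        return
    n_vis = max(1, int(rng.poisson(total_pokes / pokes_per_visit)))
    starts = np.sort(rng.random(n_vis) * (t1 - t0 - 120.0) + t0)
    pokes = rng.multinomial(total_pokes, np.full(n_vis, 1.0 / n_vis))
    if licks_per_poke > 0:
        licks = rng.poisson(licks_per_poke * pokes)
        licks[pokes == 0] = 0
    else:
        licks = np.zeros(n_vis, np.int64)
    durs = 2.0 + 0.5 * pokes + 0.15 * licks
    durs = np.minimum(durs, t1 - starts - 1e-3)
    intents.add(starts, durs, corner_code, pokes, licks)


def _motivation_visits(rng, cfg, intents, w, trait_m, ladder_steps):
    """Progressive-ratio responding: the animal completes 10 sets at each
    ladder level up to a trait-determined target level, then a partial count
    of sets at the target, never advancing past it."""
    target = int(min(len(ladder_steps) - 1,
                     np.floor(cfg.breakpoint_gain * softplus(trait_m))))
    reqs = []
    for lvl in range(target + 1):
        n_sets = 10 if lvl < target else int(rng.integers(0, 10))
        for _ in range(n_sets):
            if rng.random() < 0.3 and ladder_steps[lvl] > 1:
                # a failed attempt in its own visit (burst broken by leaving)
                reqs.append((int(rng.integers(1, ladder_steps[lvl])), False))
            reqs.append((ladder_steps[lvl], True))
    if not reqs:
        return
    n = len(reqs)
    starts = np.sort(rng.random(n) * (w.span_s - 900.0) + w.start_s + 60.0)
    pokes = np.array([r for r, _ in reqs], np.int64)
    rewarded = np.array([ok for _, ok in reqs])
    licks = np.where(rewarded, rng.poisson(cfg.licks_per_reward, n), 0)
    durs = 2.0 + 0.4 * pokes + 0.15 * licks
    intents.add(starts, durs, _REWARD, pokes, licks)


def _extinction_visits(rng, cfg, intents, w, trait_e):
    """Daily nosepoke counts Poisson(level * exp(-decay * day)); the decay is
    slower for higher extinction traits (impaired extinction)."""
    level = cfg.extinction_level_scale * float(softplus(trait_e))
    decay = float(np.clip(cfg.extinction_decay_per_day * np.exp(-0.35 * trait_e),
                          0.02, 3.0))
    for day in range(7):
        t0 = w.start_s + day * DAY_S
        n = int(rng.poisson(level * np.exp(-decay * day)))
        _count_driven_visits(rng, intents, t0, t0 + DAY_S, _REWARD, n)


def _persistence_visits(rng, cfg, intents, w, trait_p):
    """Six 6-h active (A) and six 6-h non-active (nA) periods, A first.
    nA responding scales with the persistence trait; A responding is
    rewarded, trait-free baseline."""
    block = w.span_s / 12.0
    na_total = int(rng.poisson(cfg.persistence_scale * float(softplus(trait_p))))
    a_total = int(rng.poisson(cfg.persistence_active_pokes))
    na_split = rng.multinomial(na_total, np.full(6, 1 / 6))
    a_split = rng.multinomial(a_total, np.full(6, 1 / 6))
    for i in range(12):
        t0 = w.start_s + i * block
        if i % 2 == 0:  # active
            _count_driven_visits(rng, intents, t0, t0 + block, _REWARD,
                                 int(a_split[i // 2]),
                                 licks_per_poke=cfg.licks_per_reward)
        else:
            _count_driven_visits(rng, intents, t0, t0 + block, _REWARD,
                                 int(na_split[i // 2]))


def _relapse_visits(rng, cfg, intents, w, trait_ar):
    """First relapse day: trait-scaled total lick count distributed over
    drinking visits; later days revert to background drinking."""
    day1_end = min(w.start_s + DAY_S, w.end_s)
    total_licks = int(rng.poisson(cfg.relapse_licks_scale * float(softplus(trait_ar))))
    n_vis = max(3, int(rng.poisson(12.0)))
    starts = np.sort(rng.random(n_vis) * (day1_end - w.start_s - 120.0) + w.start_s)
    licks = rng.multinomial(total_licks, np.full(n_vis, 1.0 / n_vis))
    pokes = np.maximum(rng.poisson(cfg.nosepokes_per_visit, n_vis), (licks > 0))
    durs = 2.0 + 0.5 * pokes + 0.1 * licks
    durs = np.minimum(durs, day1_end - starts - 1e-3)
    intents.add(starts, durs.astype(float), _REWARD, pokes.astype(np.int64),
                licks.astype(np.int64))
    if w.end_s > day1_end:
        _background_visits(rng, cfg, intents, day1_end, w.end_s, _REWARD,
                           cfg.licks_per_reward)


def _enforce_min_gap(x, gap):
    if len(x) < 2:
        return x
    k = np.arange(len(x)) * gap
    return np.maximum.accumulate(x - k) + k


def _animal_events(rng, cfg, schedule, animal_id, traits, ladder_steps):
    """Generate the full event stream of one animal as column arrays."""
    t_m, t_e, t_cr, t_ar, t_p = traits
    intents = _Intents()
    for w in schedule.windows:
        # water-corner background everywhere
        _background_visits(rng, cfg, intents, w.start_s, w.end_s, _WATER,
                           cfg.licks_per_water_poke)
        if w.phase in ("adaptation", "initiation_4", "initiation_8",
                       "initiation_12", "free_access"):
            _background_visits(rng, cfg, intents, w.start_s, w.end_s, _REWARD,
                               cfg.licks_per_reward)
        elif w.phase == "motivation":
            _motivation_visits(rng, cfg, intents, w, t_m, ladder_steps)
        elif w.phase == "persistence":
            _persistence_visits(rng, cfg, intents, w, t_p)
        elif w.phase == "extinction":
            _extinction_visits(rng, cfg, intents, w, t_e)
        elif w.phase == "cue_relapse":
            n = int(rng.poisson(cfg.cue_scale * float(softplus(t_cr))))
            _count_driven_visits(rng, intents, w.start_s, w.end_s, _REWARD, n)
        elif w.phase == "alcohol_relapse":
            _relapse_visits(rng, cfg, intents, w, t_ar)

    start, dur, corner, pokes, licks = intents.arrays()
    n_vis = len(start)
    if n_vis == 0:
        return (np.empty(0), np.empty(0, np.uint8), np.empty(0, np.uint8),
                np.empty(0, np.uint8), np.empty(0, np.int64))
    order = np.argsort(start, kind="stable")
    start, dur = start[order], dur[order]
    corner, pokes, licks = corner[order], pokes[order], licks[order]
    start = _enforce_min_gap(start, 1e-2)
    end = start + np.maximum(dur, 1e-4)
    end[:-1] = np.minimum(end[:-1], start[1:] - 1e-3)
    end = np.maximum(end, start + 1e-4)

    seq = np.arange(1, n_vis + 1, dtype=np.int64)
    side_vis = np.where(rng.random(n_vis) < 0.5, _LEFT, _RIGHT).astype(np.uint8)

    slots = pokes + licks
    tot = int(slots.sum())
    vis_idx = np.repeat(np.arange(n_vis), slots)
    k = np.arange(tot) - np.repeat(np.cumsum(slots) - slots, slots) + 1
    t_in = start[vis_idx] + (end - start)[vis_idx] * (k / (slots[vis_idx] + 1))
    # kind codes: 0 visit_start, 1 nosepoke, 2 lick, 3 visit_end
    kind_in = np.where(k <= pokes[vis_idx], 1, 2).astype(np.uint8)

    timestamp = np.concatenate([start, t_in, end])
    kind = np.concatenate([
        np.zeros(n_vis, np.uint8), kind_in, np.full(n_vis, 3, np.uint8),
    ])
    corner_all = np.concatenate([corner, corner[vis_idx], corner])
    side_all = np.concatenate([
        np.full(n_vis, _NONE, np.uint8), side_vis[vis_idx],
        np.full(n_vis, _NONE, np.uint8),
    ])
    seq_all = np.concatenate([seq, seq[vis_idx], seq])
    return timestamp, corner_all, side_all, kind, seq_all


# ---------------------------------------------------------------------- #
# cohort
# ---------------------------------------------------------------------- #

def simulate_cohort(config: SimConfig, validate: bool = True
                    ) -> tuple[EventLog, LatentTruth]:
    """Simulate a cohort; deterministic given ``config`` (incl. its seed).

    Returns the event log (canonically sorted, validated when ``validate``)
    and the per-animal latent ground truth.
    """
    from .behavioral_indices import RatioLadder  # default PR ladder

    cfg = config.validate()
    n = cfg.n_animals
    schedule = default_schedule()
    ladder_steps = RatioLadder().steps

    cohort_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    ids = [f"M{i + 1:04d}" for i in range(n)]
    is_prone = cohort_rng.random(n) < cfg.prone_fraction
    z = cohort_rng.standard_normal((n, 5))
    traits = np.empty((n, 5))
    for cls, mask in (("prone", is_prone), ("resistant", ~is_prone)):
        rho = cfg.rho_prone if cls == "prone" else cfg.rho_resistant
        mean = np.asarray(cfg.trait_mean_prone if cls == "prone"
                          else cfg.trait_mean_resistant, float)
        sd = np.asarray(cfg.trait_sd, float)
        cov = equicorrelation(rho) * np.outer(sd, sd)
        L = np.linalg.cholesky(cov)
        traits[mask] = mean + z[mask] @ L.T
    weights = np.clip(cohort_rng.normal(cfg.body_weight_mean_g,
                                        cfg.body_weight_sd_g, n), 15.0, None)

    chunks = []
    for i, aid in enumerate(ids):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1, i)))
        t, c, sd_, kd, sq = _animal_events(rng, cfg, schedule, aid, traits[i],
                                           ladder_steps)
        a = np.full(len(t), i, np.int64)
        chunks.append((a, t, c, sd_, kd, sq))

    if chunks:
        a, t, c, sd_, kd, sq = (np.concatenate(x) for x in zip(*chunks))
    else:
        a = sq = np.empty(0, np.int64)
        t = np.empty(0)
        c = sd_ = kd = np.empty(0, np.uint8)
    # canonical order: (animal, timestamp, visit_start < nosepoke < lick <
    # visit_end) — kind codes are already in that order
    order = np.lexsort((kd, t, a))
    events = pd.DataFrame({
        "animal_id": pd.Categorical.from_codes(a[order], categories=ids),
        "timestamp_s": t[order],
        "corner": pd.Categorical.from_codes(c[order], categories=_CORNER_CATS),
        "side": pd.Categorical.from_codes(sd_[order], categories=_SIDE_CATS),
        "kind": pd.Categorical.from_codes(kd[order], categories=_KIND_CATS),
        "visit_seq": sq[order],
    })
    registry = pd.DataFrame({
        "animal_id": ids,
        "body_weight_g": np.round(weights, 1),
        "cohort": ["sim"] * n,
    })
    log = EventLog(events=events, registry=registry, schedule=schedule)
    if validate:
        log.validate()

    truth = pd.DataFrame({"animal_id": ids,
                          "latent_class": np.where(is_prone, "prone", "resistant")})
    for j, t in enumerate(TRAIT_NAMES):
        truth[f"trait_{t}"] = traits[:, j] if n else pd.Series(dtype=float)
    return log, LatentTruth(truth)


def write_cohort(log: EventLog, truth: LatentTruth, out_dir) -> dict[str, Path]:
    """Write events/registry/schedule/truth CSVs into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv"
             for name in ("events", "registry", "schedule", "truth")}
    write_event_log(log, paths["events"], paths["schedule"], paths["registry"])
    truth.to_csv(paths["truth"])
    return paths
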