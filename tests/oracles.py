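"""Independent reference implementations used only by the tests.

These are deliberately written with a different structure from the package
code (burst-first grouping instead of poke-by-poke replay; explicit rank
arithmetic instead of library calls) so they can serve as oracles.
"""

from __future__ import annotations

import numpy as np


def brute_force_breakpoint(t, visit, steps, sets_to_advance=10, max_gap=1.0,
                           mode="requirement"):
    """Reference progressive-ratio simulator.

    Groups the poke stream into maximal bursts (same visit, consecutive gaps
    below ``max_gap``), then walks the bursts consuming requirement-sized
    sets; the requirement advances after ``sets_to_advance`` sets.
    """
    t = np.asarray(t, float)
    visit = np.asarray(visit)
    order = np.argsort(t, kind="stable")
    t, visit = t[order], visit[order]

    bursts = []
    for i in range(len(t)):
        new = (
            i == 0
            or visit[i] != visit[i - 1]
            or (t[i] - t[i - 1]) >= max_gap
        )
        if new:
            bursts.append(0)
        bursts[-1] += 1

    level = 0
    sets_done = 0
    last_completed = None
    for size in bursts:
        remaining = size
        while remaining >= steps[level]:
            remaining -= steps[level]
            sets_done += 1
            last_completed = level
            if sets_done >= sets_to_advance and level < len(steps) - 1:
                level += 1
                sets_done = 0
    if mode == "last_completed":
        return steps[last_completed] if last_completed is not None else steps[0]
    return steps[level]


def random_poke_stream(rng, max_visits=30, max_burst=40):
    """A random motivation-phase poke stream: (times, visit ids)."""
    times, visits = [], []
    t = 0.0
    for v in range(1, int(rng.integers(0, max_visits + 1)) + 1):
        t += float(rng.uniform(5.0, 60.0))
        n_runs = int(rng.integers(1, 4))
        for _ in range(n_runs):
            n = int(rng.integers(0, max_burst + 1))
            for _ in range(n):
                gap = float(rng.uniform(0.05, 0.95)) if rng.random() < 0.8 \
                    else float(rng.uniform(1.0, 4.0))
                t += gap
                times.append(t)
                visits.append(v)
            t += float(rng.uniform(1.2, 10.0))  # leave/idle between runs
    return np.asarray(times), np.asarray(visits)


def spearman_by_hand(x, y):
    """Spearman r via explicit average ranks and the Pearson formula."""
    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2.0 + 1.0  # average rank, 1-based
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2)))
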