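"""Independent brute-force oracles used to validate the optimized paths.

These deliberately re-derive results from first principles with plain
loops: an exhaustive extremum scan (candidate local extrema, contour-based
prominence, priority-ordered spacing, alternation), and an exhaustive
minimum-cost event assignment.  They share only the smoothing and
parabolic-interpolation helpers with the package, since those are
deterministic pre/post-processing, not the logic under test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from thermoresp.respiration import Extrema, moving_average, parabolic_refine
from thermoresp.trace import SampledTrace


def _local_maxima(s: np.ndarray) -> list[int]:
    return [i for i in range(1, len(s) - 1) if s[i - 1] < s[i] > s[i + 1]]


def _prominence(s: np.ndarray, i: int) -> float:
    """Standard topographic prominence: height above the higher of the two
    lowest contours reachable without climbing above the peak."""
    left_min = s[i]
    j = i - 1
    while j >= 0 and s[j] <= s[i]:
        left_min = min(left_min, s[j])
        j -= 1
    right_min = s[i]
    j = i + 1
    while j < len(s) and s[j] <= s[i]:
        right_min = min(right_min, s[j])
        j += 1
    return s[i] - max(left_min, right_min)


def _spacing_filter(s: np.ndarray, idx: list[int], distance: int) -> list[int]:
    """Keep higher extrema first; drop any within `distance` of a kept one."""
    if not idx:
        return []
    order = np.argsort(np.asarray([s[i] for i in idx]), kind="stable")[::-1]
    keep = np.ones(len(idx), dtype=bool)
    for k in order:
        if not keep[k]:
            continue
        for j in range(len(idx)):
            if j != k and keep[j] and abs(idx[j] - idx[k]) < distance:
                if s[idx[j]] <= s[idx[k]]:
                    keep[j] = False
    return [i for i, k in zip(idx, keep) if k]


def brute_force_extrema(trace: SampledTrace, smooth_window: float = 0.15,
                        min_prominence_frac: float = 0.3,
                        refractory: float = 0.6) -> Extrema:
    """Exhaustive-scan counterpart of ``detect_extrema``."""
    s = moving_average(trace.values, round(smooth_window * trace.fs))
    amp = np.percentile(s, 90) - np.percentile(s, 10)
    thr = min_prominence_frac * amp
    distance = max(int(round(refractory * trace.fs)), 1)

    events = []  # (index, kind, prominence)
    for sig, kind in ((s, "peak"), (-s, "trough")):
        cand = _spacing_filter(sig, _local_maxima(sig), distance)
        for i in cand:
            p = _prominence(sig, i)
            if p >= thr:
                events.append((i, kind, p))
    events.sort()

    # alternation: drop the lower-prominence of consecutive same-kind events
    changed = True
    while changed:
        changed = False
        for j in range(len(events) - 1):
            if events[j][1] == events[j + 1][1]:
                drop = j + 1 if events[j][2] >= events[j + 1][2] else j
                del events[drop]
                changed = True
                break
    idx = np.array([e[0] for e in events], dtype=int)
    kinds = np.array([e[1] for e in events])
    times = parabolic_refine(s, idx, trace.fs, trace.t0)
    return Extrema(times=times, kinds=kinds)


def assignment_match(thermo: np.ndarray, chest: np.ndarray,
                     tolerance: float) -> list[tuple[int, int]]:
    """Exhaustive optimal matching: maximum cardinality, then minimum total
    absolute delay, via the Hungarian algorithm on a padded cost matrix."""
    thermo = np.asarray(thermo, float)
    chest = np.asarray(chest, float)
    if len(thermo) == 0 or len(chest) == 0:
        return []
    big = 1e6
    cost = np.abs(thermo[:, None] - chest[None, :])
    cost = np.where(cost <= tolerance, cost, big)
    rows, cols = linear_sum_assignment(cost)
    return sorted((int(i), int(j)) for i, j in zip(rows, cols)
                  if cost[i, j] < big)
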