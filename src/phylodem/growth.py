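"""Per-millennium growth rates from a skyline trajectory, growth onset,
fastest-growth interval, and cross-population expansion pulses.

For consecutive grid times t1 (older) and t2 (younger) the instantaneous
growth rate per millennium is r = ln(N_t2 / N_t1) / dt with dt in kyr; a
negative r means the population was shrinking toward the present from t1.
Summed over the grid, r telescopes exactly to ln(N_present / N_oldest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .clock import NeTrajectory

__all__ = [
    "GrowthProfile",
    "PulseHistogram",
    "growth_rate_series",
    "growth_onset",
    "max_growth",
    "pulse_histogram",
]


@dataclass
class GrowthProfile:
    """Growth-rate series on a kya grid.

    times_kya[i] is the *older* endpoint of interval i; r[i] is the rate on
    (times_kya[i] ... times_kya[i] - dt). Summary fields are filled by
    growth_onset / max_growth; NaN where undefined."""

    times_kya: np.ndarray
    r: np.ndarray
    dt_kyr: float
    onset_kya: float = math.nan
    t_max_kya: float = math.nan
    r_max: float = math.nan
    fastest_interval: tuple[float, float] | None = None
    tie_at_max: bool = False


@dataclass
class PulseHistogram:
    bin_edges: np.ndarray  # kya
    counts: np.ndarray
    clusters: list[tuple[float, float]]  # (min_kya, max_kya), ordered young->old
    gap_threshold: float


def growth_rate_series(traj: NeTrajectory) -> GrowthProfile:
    """Instantaneous growth rate per millennium at every grid interval."""
    t_kya = traj.times_kya
    N = traj.values
    if np.any(N <= 0):
        raise ValueError("trajectory values must be positive")
    dt = np.diff(t_kya)
    # interval i spans (t[i] young, t[i+1] old): r = ln(N_young/N_old)/dt
    r = np.log(N[:-1] / N[1:]) / dt
    return GrowthProfile(times_kya=t_kya[1:], r=r, dt_kyr=float(dt[0]))


def growth_onset(profile: GrowthProfile, persistence: int = 3) -> float:
    """Oldest grid time where growth starts and persists.

    Scanning from oldest to youngest, the onset is the oldest time t with
    r(t) > 0 and r > 0 over the next `persistence` younger grid intervals
    (suppresses single-step skyline noise). NaN if no such time exists.
    """
    r = profile.r
    onset = math.nan
    # r is ordered young -> old; the persistence window for interval i is
    # the `persistence` younger intervals i-1 ... i-persistence
    for i in range(r.size - 1, persistence - 1, -1):
        if r[i] > 0 and np.all(r[i - persistence : i] > 0):
            onset = float(profile.times_kya[i])
            break
    profile.onset_kya = onset
    return onset


def max_growth(profile: GrowthProfile, beta: float = 0.5):
    """Time and value of the maximum growth rate, and the fastest interval.

    t_max is the older endpoint of the argmax interval (ties go to the
    youngest occurrence, flagged); the fastest interval is the maximal
    contiguous run containing t_max with r >= beta * r_max, reported as
    (older_kya, younger_kya).
    """
    r = profile.r
    if np.all(r <= 0) or r.size == 0:
        profile.t_max_kya = math.nan
        profile.r_max = math.nan
        profile.fastest_interval = None
        return math.nan, math.nan, None
    r_max = float(np.max(r))
    argmaxes = np.flatnonzero(r >= r_max - 1e-15)
    idx = int(argmaxes[0])  # times ascend toward the past: first = youngest
    profile.tie_at_max = len(argmaxes) > 1
    t_max = float(profile.times_kya[idx])

    lo = hi = idx
    threshold = beta * r_max
    while lo > 0 and r[lo - 1] >= threshold:
        lo -= 1
    while hi < r.size - 1 and r[hi + 1] >= threshold:
        hi += 1
    older = float(profile.times_kya[hi])
    younger = float(profile.times_kya[lo] - profile.dt_kyr)
    profile.t_max_kya = t_max
    profile.r_max = r_max
    profile.fastest_interval = (older, max(younger, 0.0))
    return t_max, r_max, profile.fastest_interval


def pulse_histogram(values, bin_kyr: float = 1.0, gap_threshold: float = 10.0) -> PulseHistogram:
    """Histogram and gap-clustering of per-population times at maximum growth.

    Clusters are maximal runs of the sorted values whose consecutive gaps
    are <= gap_threshold (kyr); each input value lands in exactly one bin
    and one cluster.
    """
    values = np.asarray([v for v in values if math.isfinite(v)], dtype=float)
    if values.size == 0:
        raise ValueError("need at least one finite value")
    lo = math.floor(values.min() / bin_kyr) * bin_kyr
    hi = math.ceil(values.max() / bin_kyr) * bin_kyr
    if hi <= lo:
        hi = lo + bin_kyr
    edges = np.arange(lo, hi + bin_kyr, bin_kyr)
    counts, _ = np.histogram(values, bins=edges)

    ordered = np.sort(values)
    clusters = []
    start = ordered[0]
    prev = ordered[0]
    for v in ordered[1:]:
        if v - prev > gap_threshold:
            clusters.append((float(start), float(prev)))
            start = v
        prev = v
    clusters.append((float(start), float(prev)))
    return PulseHistogram(
        bin_edges=edges, counts=counts, clusters=clusters, gap_threshold=gap_threshold
    )
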