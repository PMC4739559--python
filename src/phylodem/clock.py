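"""Strict-clock distance genealogies, TMRCA calibration, classic skyline.

A deterministic desk-scale pipeline for dating and demographic trajectories:
an average-linkage (UPGMA) ultrametric tree on uncorrected p-distances plays
the strict-clock genealogy; the root height in substitutions/site divided by
the per-lineage clock rate gives the TMRCA; the classic/generalized skyline
turns inter-coalescent intervals into a stepwise effective-size trajectory
(scaled by generation time, which mtDNA data alone cannot resolve).

The clock rate ships as a *pairwise divergence* rate of 1.82%/Myr (a
cyprinid cytochrome-b calibration); the per-lineage rate is half of that.
Whether published calibrations of this kind are per-lineage or pairwise is
often ambiguous - the convention used here is explicit and adjustable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .diversity import analyzed_site_mask
from .errors import DegenerateInputError
from .genealogy import Genealogy, Node
from .io import Alignment

__all__ = [
    "ClockConfig",
    "NeTrajectory",
    "p_distance_matrix",
    "clock_tree",
    "tmrca_kya",
    "calibrate",
    "classic_skyline",
]

DEFAULT_DIVERGENCE_RATE = 0.0182  # substitutions/site/Myr between lineage pairs


@dataclass(frozen=True)
class ClockConfig:
    """Strict molecular clock. divergence_rate is substitutions/site/Myr
    separating a pair of lineages; lineage_rate is exactly half."""

    divergence_rate: float = DEFAULT_DIVERGENCE_RATE

    @property
    def lineage_rate(self) -> float:
        return self.divergence_rate / 2.0

    @property
    def lineage_rate_per_year(self) -> float:
        return self.lineage_rate / 1e6


@dataclass
class NeTrajectory:
    """Scaled effective size (Ne x generation time, consistent units) on a
    regular grid of years before present, youngest first.

    step_times/step_values keep the raw (un-resampled) skyline steps:
    step_values[i] applies on [step_times[i], step_times[i+1])."""

    times: np.ndarray  # years before present, starting at 0, increasing
    values: np.ndarray
    grid_step: float
    step_times: np.ndarray | None = None
    step_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times[0] != 0.0:
            raise ValueError("trajectory must start at time 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("trajectory values must be positive")

    @property
    def times_kya(self) -> np.ndarray:
        return self.times / 1000.0


# ---------------------------------------------------------------------------
# Distance clock tree (UPGMA with deterministic tie-breaks)
# ---------------------------------------------------------------------------

def p_distance_matrix(a: Alignment, correction: str | None = None, per_site: bool = True) -> np.ndarray:
    """Pairwise distances on analyzed sites (complete deletion).

    correction=None gives raw p-distances; 'jc' applies the Jukes-Cantor
    multiple-hit correction (shallow intraspecific data rarely need it).
    """
    mask = analyzed_site_mask(a)
    if not mask.any():
        raise DegenerateInputError("complete deletion removed every site")
    mat = a.matrix()[:, mask]
    L = mat.shape[1]
    n = a.n
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1 :] = (mat[i + 1 :] != mat[i]).sum(axis=1)
    d = d + d.T
    if per_site:
        d = d / L
    if correction == "jc":
        if np.any(d >= 0.75):
            raise ValueError("JC correction undefined at p >= 0.75")
        d = -0.75 * np.log1p(-4.0 * d / 3.0)
    elif correction is not None:
        raise ValueError("correction must be None or 'jc'")
    return d


def clock_tree(a: Alignment, correction: str | None = None) -> Genealogy:
    """Average-linkage ultrametric tree on pairwise p-distances.

    Joins the pair with minimum average distance; ties are broken
    lexicographically by the smallest member label of each cluster. Node
    heights are half the joining distance (substitutions/site).
    """
    if a.n < 2:
        raise ValueError("need n >= 2")
    d = p_distance_matrix(a, correction=correction)
    nodes = [Node(label=name, height=0.0) for name in a.ids]
    sizes = [1] * a.n
    min_labels = list(a.ids)
    active = list(range(a.n))
    dist = d.astype(float).copy()

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (
                    dist[i, j],
                    *sorted((min_labels[i], min_labels[j])),
                )
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        new_height = dist[i, j] / 2.0
        parent = Node(height=new_height, children=[nodes[i], nodes[j]])
        # average-linkage update against every other active cluster
        for k in active:
            if k in (i, j):
                continue
            dik, djk = dist[i, k], dist[j, k]
            merged = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[i, k] = dist[k, i] = merged
        nodes[i] = parent
        sizes[i] += sizes[j]
        min_labels[i] = min(min_labels[i], min_labels[j])
        active.remove(j)
    return Genealogy(nodes[active[0]])


def tmrca_kya(g: Genealogy, clock: ClockConfig = ClockConfig()) -> float:
    """TMRCA in kya from a tree whose heights are substitutions/site."""
    years = g.tmrca / clock.lineage_rate_per_year
    return years / 1000.0


def calibrate(g: Genealogy, clock: ClockConfig = ClockConfig()) -> Genealogy:
    """Rescale a substitutions/site tree to years before present."""
    return g.scaled(1.0 / clock.lineage_rate_per_year)


# ---------------------------------------------------------------------------
# Classic / generalized skyline
# ---------------------------------------------------------------------------

def classic_skyline(
    g: Genealogy,
    epsilon: float = 0.0,
    grid_step: float = 1000.0,
) -> NeTrajectory:
    """Skyline trajectory from a calibrated genealogy (heights in years).

    For the interval with k extant lineages and duration w the classic
    estimate of the scaled size is k(k-1)w/2. With epsilon > 0, adjacent
    intervals are pooled (generalized skyline) while the composite width is
    below epsilon; a pooled group spanning widths w_i with c coalescent
    events estimates (sum_i k_i (k_i - 1) w_i / 2) / c. The step function is
    resampled onto a regular grid (default 1 kyr).
    """
    intervals = g.coalescent_intervals()
    # pool: greedily accumulate intervals until composite width >= epsilon
    pooled: list[tuple[float, float]] = []  # (width, estimate)
    buf_w, buf_stat, buf_c = 0.0, 0.0, 0
    for idx, (k, w) in enumerate(intervals):
        buf_w += w
        buf_stat += k * (k - 1) * w / 2.0
        buf_c += 1
        last = idx == len(intervals) - 1
        if buf_w >= epsilon or last:
            if buf_w > 0:
                pooled.append((buf_w, buf_stat / buf_c))
            buf_w, buf_stat, buf_c = 0.0, 0.0, 0
    if not pooled:
        raise ValueError("degenerate genealogy: zero total depth")

    step_times = np.concatenate([[0.0], np.cumsum([w for w, _ in pooled])])
    step_values = np.array([m for _, m in pooled])
    step_values = np.maximum(step_values, np.finfo(float).tiny)

    root = step_times[-1]
    grid = np.arange(0.0, root + grid_step, grid_step)
    idx = np.clip(np.searchsorted(step_times, grid, side="right") - 1, 0, len(step_values) - 1)
    values = step_values[idx]
    return NeTrajectory(
        times=grid,
        values=values,
        grid_step=grid_step,
        step_times=step_times,
        step_values=step_values,
    )
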