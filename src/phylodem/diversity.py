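"""Molecular diversity indices: haplotype diversity h (with SD), mean
pairwise differences, nucleotide diversity pi, segregating sites.

Missing data are handled by complete deletion by default: any column
containing '-' or 'N' in any sequence is removed before analysis
(switchable to pairwise deletion for distances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .io import Alignment

__all__ = [
    "HaplotypeTable",
    "DiversitySummary",
    "analyzed_site_mask",
    "collapse_haplotypes",
    "haplotype_diversity",
    "mean_pairwise_differences",
    "nucleotide_diversity",
    "segregating_sites",
    "diversity_summary",
]


@dataclass
class HaplotypeTable:
    """Distinct sequences with multiplicities, on analyzed sites only.

    counts are sorted descending (ties by first occurrence); assignment maps
    each sequence id to its haplotype index.
    """

    haplotypes: tuple[str, ...]
    counts: np.ndarray
    assignment: dict[str, int]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Hamming distances (differing sites) between haplotypes."""
        mat = np.array([list(h) for h in self.haplotypes], dtype="U1")
        H = mat.shape[0]
        d = np.zeros((H, H), dtype=int)
        for i in range(H):
            d[i, i + 1:] = (mat[i + 1:] != mat[i]).sum(axis=1)
        return d + d.T


def analyzed_site_mask(a: Alignment) -> np.ndarray:
    """Boolean mask of columns free of '-' and 'N' in every sequence."""
    mat = a.matrix()
    return ~np.any((mat == "-") | (mat == "N"), axis=0)


def collapse_haplotypes(a: Alignment) -> HaplotypeTable:
    """Collapse an alignment into distinct haplotypes.

    Identity is judged on analyzed sites only (complete deletion). Counts are
    sorted descending, ties broken by first occurrence in the alignment.
    """
    mask = analyzed_site_mask(a)
    if not mask.any():
        raise DegenerateInputError("complete deletion removed every site")
    mat = a.matrix()[:, mask]
    reduced = ["".join(row) for row in mat]
    first_seen: dict[str, int] = {}
    raw_counts: dict[str, int] = {}
    for idx, h in enumerate(reduced):
        if h not in first_seen:
            first_seen[h] = idx
        raw_counts[h] = raw_counts.get(h, 0) + 1
    ordered = sorted(raw_counts, key=lambda h: (-raw_counts[h], first_seen[h]))
    index = {h: i for i, h in enumerate(ordered)}
    assignment = {a.ids[i]: index[reduced[i]] for i in range(a.n)}
    return HaplotypeTable(
        haplotypes=tuple(ordered),
        counts=np.array([raw_counts[h] for h in ordered], dtype=int),
        assignment=assignment,
    )


def haplotype_diversity(counts) -> tuple[float, float]:
    """Unbiased haplotype diversity h and its standard deviation.

    h = n (1 - sum p_i^2) / (n - 1); the variance is Nei's standard
    estimator
    (2 / (n (n-1))) * {2 (n-2) [sum p_i^3 - (sum p_i^2)^2]
                       + sum p_i^2 - (sum p_i^2)^2}.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = counts / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    h = n * (1.0 - s2) / (n - 1.0)
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2
    )
    return h, math.sqrt(max(var, 0.0))


def _pairwise_difference_total(table: HaplotypeTable) -> float:
    """Sum of pairwise differences over all sequence pairs via haplotypes."""
    d = table.distance_matrix()
    c = table.counts.astype(float)
    # between-haplotype pairs only; within-haplotype pairs contribute 0
    return float(c @ d @ c) / 2.0


def mean_pairwise_differences(a: Alignment) -> float:
    """Mean number of differing analyzed sites over all sequence pairs."""
    if a.n < 2:
        raise ValueError("need n >= 2")
    table = collapse_haplotypes(a)
    n = a.n
    return _pairwise_difference_total(table) / (n * (n - 1) / 2.0)


def nucleotide_diversity(a: Alignment) -> float:
    """Per-site nucleotide diversity: mean pairwise differences / analyzed length."""
    if a.n < 2:
        raise ValueError("need n >= 2")
    n_sites = int(analyzed_site_mask(a).sum())
    if n_sites == 0:
        raise DegenerateInputError("complete deletion removed every site")
    return mean_pairwise_differences(a) / n_sites


def segregating_sites(a: Alignment) -> int:
    """Number of polymorphic analyzed sites."""
    mask = analyzed_site_mask(a)
    if not mask.any():
        raise DegenerateInputError("complete deletion removed every site")
    mat = a.matrix()[:, mask]
    return int(np.sum(np.any(mat != mat[0], axis=0)))


@dataclass
class DiversitySummary:
    h: float
    sd_h: float
    p: float  # mean pairwise differences
    pi: float  # per-site nucleotide diversity
    S: int
    n_hap: int
    n: int


def diversity_summary(a: Alignment) -> DiversitySummary:
    table = collapse_haplotypes(a)
    h, sd_h = haplotype_diversity(table.counts)
    p = mean_pairwise_differences(a)
    return DiversitySummary(
        h=h,
        sd_h=sd_h,
        p=p,
        pi=nucleotide_diversity(a),
        S=segregating_sites(a),
        n_hap=table.n_haplotypes,
        n=a.n,
    )
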