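"""Tajima's D and Fu's Fs neutrality tests with coalescent p-values.

Both statistics are strongly negative after a recent demographic expansion:
D contrasts mean pairwise differences with Watterson's S/a1, Fs is the
log-odds of seeing at least the observed number of haplotypes under the
Ewens sampling formula at theta = mean pairwise differences.

The Ewens haplotype-number distribution is evaluated in log space through
the unsigned Stirling numbers of the first kind, which keeps Fs stable for
samples up to at least n = 1200.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .diversity import collapse_haplotypes, mean_pairwise_differences, segregating_sites
from .io import Alignment
from .simulate import Demography, mutate_infinite_sites, simulate_genealogy

__all__ = [
    "NeutralitySummary",
    "tajimas_d",
    "tajimas_d_from_counts",
    "log_stirling1_row",
    "ewens_haplotype_log_pmf",
    "fus_fs",
    "fus_fs_from_counts",
    "neutrality_summary",
    "neutrality_pvalues",
]


@dataclass
class NeutralitySummary:
    """Observed test statistics for one sample.

    D and Fs are NaN (undefined) for monomorphic samples; p-values are
    attached by `neutrality_pvalues`.
    """

    n: int
    S: int
    k_hat: float
    n_hap: int
    D: float
    Fs: float
    p_D: float = math.nan
    p_Fs: float = math.nan


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajimas_d_from_counts(n: int, S: int, k_hat: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences, using the standard constants:

    a1 = sum_{i<n} 1/i, a2 = sum 1/i^2, b1 = (n+1)/(3(n-1)),
    b2 = 2(n^2+n+3)/(9n(n-1)), c1 = b1 - 1/a1,
    c2 = b2 - (n+2)/(a1 n) + a2/a1^2, e1 = c1/a1, e2 = c2/(a1^2 + a2),
    D = (k_hat - S/a1) / sqrt(e1 S + e2 S (S-1)).
    """
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S == 0:
        return math.nan
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1.0))


def tajimas_d(a: Alignment) -> float:
    return tajimas_d_from_counts(a.n, segregating_sites(a), mean_pairwise_differences(a))


# ---------------------------------------------------------------------------
# Fu's Fs via the Ewens sampling formula
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def log_stirling1_row(n: int) -> np.ndarray:
    """log |S1(n, k)| for k = 0..n (unsigned Stirling, first kind).

    Recurrence |S1(n,k)| = |S1(n-1,k-1)| + (n-1) |S1(n-1,k)|, carried in
    log space row by row.
    """
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S1(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1:] = row[:-1]  # |S1(m-1, k-1)| term
        if m > 1:
            new = np.logaddexp(new, math.log(m - 1) + row)
        row = new
    return row


def ewens_haplotype_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 0..n under the Ewens sampling formula:
    P(K=k) = |S1(n,k)| theta^k / (theta (theta+1) ... (theta+n-1)).
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    log_s1 = log_stirling1_row(n)
    k = np.arange(n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return log_s1 + k * math.log(theta) - log_rising


def fus_fs_from_counts(n: int, k_obs: int, theta: float) -> float:
    """Fs = ln(S' / (1 - S')) with S' = P(K >= k_obs) at theta = k_hat."""
    if n < 2:
        raise ValueError("need n >= 2")
    if theta <= 0 or k_obs < 2:
        return math.nan
    log_pmf = ewens_haplotype_log_pmf(n, theta)
    # ln(S'/(1-S')) = log P(K >= k_obs) - log P(K < k_obs); summing each
    # tail separately keeps the smaller one accurate in log space
    upper = _logsumexp(log_pmf[k_obs:])
    lower = _logsumexp(log_pmf[1:k_obs])
    return upper - lower


def _logsumexp(logs: np.ndarray) -> float:
    finite = logs[np.isfinite(logs)]
    if finite.size == 0:
        return -math.inf
    m = float(np.max(finite))
    return m + math.log(float(np.sum(np.exp(finite - m))))


def fus_fs(a: Alignment) -> float:
    table = collapse_haplotypes(a)
    k_hat = mean_pairwise_differences(a)
    return fus_fs_from_counts(a.n, table.n_haplotypes, k_hat)


def neutrality_summary(a: Alignment) -> NeutralitySummary:
    table = collapse_haplotypes(a)
    S = segregating_sites(a)
    k_hat = mean_pairwise_differences(a)
    D = tajimas_d_from_counts(a.n, S, k_hat) if a.n >= 4 else math.nan
    Fs = fus_fs_from_counts(a.n, table.n_haplotypes, k_hat)
    return NeutralitySummary(n=a.n, S=S, k_hat=k_hat, n_hap=table.n_haplotypes, D=D, Fs=Fs)


# ---------------------------------------------------------------------------
# Simulated p-values
# ---------------------------------------------------------------------------

def _simulate_null_statistics(n: int, theta: float, reps: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """D and Fs for `reps` constant-size coalescent samples at given theta
    (infinite sites). Vectorized per replicate over branches."""
    Ds = np.empty(reps)
    Fss = np.empty(reps)
    pairs_total = n * (n - 1) / 2.0
    for r in range(reps):
        g = simulate_genealogy(n, Demography(model="constant", theta1=theta), rng)
        labels, geno = mutate_infinite_sites(g, theta, rng)
        S = geno.shape[1]
        if S == 0:
            Ds[r] = math.nan
            Fss[r] = math.nan
            continue
        derived = geno.sum(axis=0)
        k_hat = float(np.sum(derived * (n - derived))) / pairs_total
        k_obs = len({row.tobytes() for row in geno})
        Ds[r] = tajimas_d_from_counts(n, S, k_hat)
        Fss[r] = fus_fs_from_counts(n, k_obs, k_hat)
    return Ds, Fss


def neutrality_pvalues(
    observed: NeutralitySummary, reps: int = 1000, seed=None, tail: str = "lower"
) -> NeutralitySummary:
    """Attach simulated p-values to an observed summary.

    Null samples are constant-size coalescent simulations at theta = k_hat
    with the same n; p is the fraction of simulated statistics <= observed
    (lower tail, the direction diagnostic of expansion) or, with
    tail='two-sided', the fraction at least as extreme in absolute value.
    """
    if reps < 100:
        raise ValueError("need reps >= 100")
    if tail not in ("lower", "two-sided"):
        raise ValueError("tail must be 'lower' or 'two-sided'")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if not math.isfinite(observed.D) and not math.isfinite(observed.Fs):
        return observed
    Ds, Fss = _simulate_null_statistics(observed.n, max(observed.k_hat, 1e-9), reps, rng)

    def pval(sim: np.ndarray, obs: float) -> float:
        if not math.isfinite(obs):
            return math.nan
        ok = sim[np.isfinite(sim)]
        if ok.size == 0:
            return math.nan
        if tail == "lower":
            return float(np.mean(ok <= obs))
        return float(np.mean(np.abs(ok) >= abs(obs)))

    observed.p_D = pval(Ds, observed.D)
    observed.p_Fs = pval(Fss, observed.Fs)
    return observed
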