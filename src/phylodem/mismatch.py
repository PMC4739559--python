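"""Mismatch distributions and the sudden-expansion model.

The observed spectrum counts sequence pairs at 0..d differences. Under the
sudden-expansion model a population at equilibrium diversity theta0 jumps to
theta1 at mutational time tau (= 2ut) before present; the expected mismatch
distribution is

    F_j(tau, theta0, theta1) = F_j(theta1) * P[Gamma(j+1) <= (1 + 1/theta1) tau]
                               + e^{-tau/theta1} * sum_m Pois(m; tau) F_{j-m}(theta0)

where F_j(theta) = theta^j / (1+theta)^{j+1} is the equilibrium (geometric)
distribution. The first term covers pairs coalescing after the expansion,
the second pairs surviving into the small ancestral population (tau extra
mutations plus an equilibrium draw at theta0). The fit minimizes the sum of
squared deviations (SSD) between observed relative frequencies and the
model over the observed classes; goodness-of-fit uses a parametric
bootstrap, and Harpending's raggedness index summarizes the smoothness of
the spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .diversity import collapse_haplotypes
from .errors import FitFailureError
from .io import Alignment
from .simulate import Demography, mutate_infinite_sites, simulate_genealogy

__all__ = [
    "MismatchFit",
    "mismatch_distribution",
    "raggedness",
    "expected_mismatch",
    "fit_sudden_expansion",
    "ssd_pvalue",
    "tau_confidence_interval",
]


@dataclass
class MismatchFit:
    spectrum: np.ndarray
    n: int
    tau: float
    theta0: float
    theta1: float
    ssd: float
    raggedness: float
    p_ssd: float = math.nan
    tau_ci: tuple[float, float] | None = None


def mismatch_distribution(a: Alignment) -> np.ndarray:
    """Counts of sequence pairs at 0..d_max differences (analyzed sites)."""
    if a.n < 2:
        raise ValueError("need n >= 2")
    table = collapse_haplotypes(a)
    d = table.distance_matrix()
    c = table.counts
    d_max = int(d.max())
    spectrum = np.zeros(d_max + 1, dtype=int)
    # within-haplotype pairs are identical
    spectrum[0] += int(np.sum(c * (c - 1) // 2))
    H = len(c)
    for i in range(H):
        for j in range(i + 1, H):
            spectrum[d[i, j]] += int(c[i] * c[j])
    return spectrum


def raggedness(spectrum) -> float:
    """Harpending's raggedness index.

    r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2 over relative frequencies x with a
    terminal zero class appended (so a monomorphic spectrum gives r = 1).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.size == 0:
        raise ValueError("empty spectrum")
    x = spectrum / spectrum.sum()
    x = np.append(x, 0.0)
    return float(np.sum(np.diff(x) ** 2))


def _equilibrium(theta: float, j: np.ndarray) -> np.ndarray:
    """Geometric equilibrium mismatch F_j(theta); handles theta = 0."""
    if theta <= 0:
        return (j == 0).astype(float)
    return np.exp(j * math.log(theta) - (j + 1) * math.log1p(theta))


def expected_mismatch(tau: float, theta0: float, theta1: float, n_classes: int) -> np.ndarray:
    """Model probabilities for difference classes 0..n_classes-1."""
    j = np.arange(n_classes)
    recent = _equilibrium(theta1, j) * special.gammainc(j + 1, (1.0 + 1.0 / theta1) * tau) \
        if tau > 0 else np.zeros(n_classes)
    if tau > 0:
        pois = stats.poisson.pmf(j, tau)
    else:
        pois = (j == 0).astype(float)
    eq0 = _equilibrium(theta0, j)
    ancestral = np.convolve(pois, eq0)[:n_classes]
    survive = math.exp(-tau / theta1) if theta1 > 0 else 0.0
    return recent + survive * ancestral


def _grid_search(observed, taus, theta0s, theta1s):
    """Vectorized SSD evaluation over the (tau, theta0, theta1) grid."""
    J = observed.size
    j = np.arange(J)
    eq0 = np.stack([_equilibrium(t0, j) for t0 in theta0s])  # (A, J)
    eq1 = np.stack([_equilibrium(t1, j) for t1 in theta1s])  # (B, J)
    admissible = theta0s[:, None] <= theta1s[None, :]  # (A, B)
    best = (np.inf, None)
    for tau in taus:
        if tau > 0:
            gain = special.gammainc(j + 1, (1.0 + 1.0 / theta1s)[:, None] * tau)  # (B, J)
            pois = stats.poisson.pmf(j, tau)
            survive = np.exp(-tau / theta1s)  # (B,)
        else:
            gain = np.zeros((theta1s.size, J))
            pois = (j == 0).astype(float)
            survive = np.ones(theta1s.size)
        # ancestral[a, j] = sum_m pois[m] eq0[a, j-m]
        ancestral = np.stack([np.convolve(pois, eq0[a])[:J] for a in range(eq0.shape[0])])
        model = eq1[None, :, :] * gain[None, :, :] + survive[None, :, None] * ancestral[:, None, :]
        ssd = np.sum((observed[None, None, :] - model) ** 2, axis=-1)  # (A, B)
        ssd = np.where(admissible, ssd, np.inf)
        a, b = np.unravel_index(np.argmin(ssd), ssd.shape)
        if ssd[a, b] < best[0]:
            best = (float(ssd[a, b]), (float(tau), float(theta0s[a]), float(theta1s[b])))
    return best


def _ssd(params: np.ndarray, observed: np.ndarray) -> float:
    tau, theta0, theta1 = params
    if tau < 0 or theta0 < 0 or theta1 <= 0 or theta0 > theta1:
        return np.inf
    model = expected_mismatch(tau, theta0, theta1, observed.size)
    return float(np.sum((observed - model) ** 2))


def fit_sudden_expansion(
    spectrum,
    n: int,
    tau_grid: int = 24,
    theta_grid: int = 8,
) -> MismatchFit:
    """Least-squares fit of (tau, theta0, theta1) to an observed spectrum.

    Coarse grid search (the SSD surface is multimodal) followed by bounded
    Nelder-Mead refinement, with the constraint 0 <= theta0 <= theta1.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if n < 4:
        raise ValueError("need n >= 4")
    if spectrum.size < 2 or spectrum.sum() <= 0:
        raise FitFailureError("degenerate mismatch spectrum")
    observed = spectrum / spectrum.sum()
    d = spectrum.size - 1
    k_hat = float(np.sum(np.arange(spectrum.size) * observed))

    taus = np.linspace(0.0, 2.0 * max(d, 1), tau_grid)
    theta0s = np.concatenate([[0.0], np.geomspace(0.01, max(k_hat, 0.1), theta_grid - 1)])
    theta1s = np.geomspace(max(k_hat, 0.1), 1e4, theta_grid)

    best = _grid_search(observed, taus, theta0s, theta1s)
    if best[1] is None:
        raise FitFailureError("grid search found no admissible point")

    res = optimize.minimize(
        _ssd,
        np.array(best[1]),
        args=(observed,),
        method="Nelder-Mead",
        bounds=[(0.0, 4.0 * max(d, 1)), (0.0, 1e5), (1e-6, 1e6)],
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    params = res.x if res.fun <= best[0] else np.array(best[1])
    ssd = min(float(res.fun), best[0])
    tau, th0, th1 = (float(v) for v in params)
    if th0 > th1:  # numerical slip at the boundary
        th0 = th1
    return MismatchFit(
        spectrum=spectrum.astype(int),
        n=n,
        tau=tau,
        theta0=th0,
        theta1=th1,
        ssd=ssd,
        raggedness=raggedness(spectrum),
    )


def _simulate_spectrum(n: int, demography: Demography, rng) -> np.ndarray:
    """Pairwise-difference spectrum of one coalescent sample (infinite sites)."""
    g = simulate_genealogy(n, demography, rng)
    _, geno = mutate_infinite_sites(g, demography.theta1, rng)
    diffs = np.zeros(n * (n - 1) // 2, dtype=int)
    if geno.shape[1]:
        idx = 0
        for i in range(n):
            block = np.sum(geno[i + 1 :] != geno[i], axis=1)
            diffs[idx : idx + block.size] = block
            idx += block.size
    spectrum = np.bincount(diffs)
    return spectrum


def ssd_pvalue(fit: MismatchFit, reps: int = 200, seed=None) -> MismatchFit:
    """Parametric-bootstrap goodness-of-fit p for the fitted expansion model.

    Coalescent samples are simulated under the fitted (tau, theta0, theta1),
    each is refitted, and p is the fraction of simulated SSDs >= observed.
    A small p (<= 0.05) rejects the sudden-expansion model. Also records the
    percentile bootstrap interval for tau.
    """
    if reps < 100:
        raise ValueError("need reps >= 100")
    if not math.isfinite(fit.ssd):
        raise FitFailureError("cannot bootstrap a failed fit")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    demog = Demography(
        model="sudden_expansion" if fit.tau > 0 else "constant",
        theta1=max(fit.theta1, 1e-6),
        theta0=float(min(max(fit.theta0, 1e-6), max(fit.theta1, 1e-6))),
        tau=fit.tau,
    )
    ssds = np.empty(reps)
    taus = np.empty(reps)
    for r in range(reps):
        spec = _simulate_spectrum(fit.n, demog, rng)
        try:
            refit = fit_sudden_expansion(spec, fit.n, tau_grid=12, theta_grid=6)
            ssds[r] = refit.ssd
            taus[r] = refit.tau
        except FitFailureError:
            ssds[r] = np.nan
            taus[r] = np.nan
    ok = np.isfinite(ssds)
    fit.p_ssd = float(np.mean(ssds[ok] >= fit.ssd - 1e-15)) if ok.any() else math.nan
    tok = taus[np.isfinite(taus)]
    if tok.size:
        fit.tau_ci = (float(np.percentile(tok, 2.5)), float(np.percentile(tok, 97.5)))
    return fit


def tau_confidence_interval(fit: MismatchFit) -> tuple[float, float] | None:
    return fit.tau_ci
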