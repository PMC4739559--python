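"""Environment-diversity correlations and whole-study orchestration.

Spearman rank correlations (midranks for ties) between environmental
covariates and per-population genetic metrics, with permutation p-values -
appropriate for the small population counts and heavily tied precipitation
values typical of these surveys. `run_study` chains every pipeline stage
over a multi-population dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clock import ClockConfig, calibrate, classic_skyline, clock_tree, tmrca_kya
from .diversity import diversity_summary
from .growth import growth_onset, growth_rate_series, max_growth, pulse_histogram
from .io import Alignment, PopulationRecord
from .mismatch import fit_sudden_expansion, mismatch_distribution, ssd_pvalue
from .neutrality import neutrality_pvalues, neutrality_summary
from .simulate import StudyDataset

__all__ = [
    "CorrelationResult",
    "StudyResult",
    "spearman",
    "permutation_pvalue",
    "correlation_table",
    "run_study",
]

COVARIATES = ("altitude", "lake_area", "basin_area", "precipitation")
METRICS = ("h", "p", "pi", "tmrca")


@dataclass
class CorrelationResult:
    metric: str
    covariate: str
    rho: float
    p_perm: float
    n_used: int


def spearman(x, y) -> float:
    """Spearman rho: product-moment correlation of midranks.

    NaN (undefined) when either vector is constant. Pairs with a missing
    value in either vector are dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    rx = stats.rankdata(x)  # midranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def permutation_pvalue(x, y, reps: int = 999, seed=None) -> tuple[float, float]:
    """Two-sided permutation p-value for Spearman rho.

    p = (1 + #{|rho_perm| >= |rho_obs|}) / (reps + 1); returns (rho, p).
    """
    if reps < 999:
        raise ValueError("need reps >= 999")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    rho_obs = spearman(x, y)
    if not math.isfinite(rho_obs):
        return rho_obs, math.nan
    # permute precomputed ranks of y; rho is rank-based so this is exact
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    denom_x = math.sqrt(float(np.sum(rx**2)))
    ry_c = ry - ry.mean()
    denom_y = math.sqrt(float(np.sum(ry_c**2)))
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(ry_c)
        rho_p = float(np.sum(rx * perm)) / (denom_x * denom_y)
        if abs(rho_p) >= abs(rho_obs) - 1e-12:
            hits += 1
    return rho_obs, (1 + hits) / (reps + 1)


def correlation_table(
    frame: pd.DataFrame,
    metrics=METRICS,
    covariates=COVARIATES,
    reps: int = 999,
    seed=None,
) -> list[CorrelationResult]:
    """All metric x covariate Spearman correlations with permutation p-values.

    `frame` holds one row per population; missing covariates are dropped
    pairwise per correlation.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for metric in metrics:
        for cov in covariates:
            if metric not in frame.columns or cov not in frame.columns:
                continue
            x = frame[cov].to_numpy(float)
            y = frame[metric].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                out.append(CorrelationResult(metric, cov, math.nan, math.nan, int(ok.sum())))
                continue
            rho, p = permutation_pvalue(x[ok], y[ok], reps=reps, seed=rng)
            out.append(CorrelationResult(metric, cov, rho, p, int(ok.sum())))
    return out


# ---------------------------------------------------------------------------
# Whole-study orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Per-population summaries plus study-level correlations and pulses."""

    per_population: pd.DataFrame
    correlations: list[CorrelationResult]
    pulses: object  # PulseHistogram, or None with < 1 finite t_max
    seed: int
    parameters: dict = field(default_factory=dict)


def run_study(
    dataset: StudyDataset | list[tuple[PopulationRecord, Alignment]],
    seed: int = 0,
    neutrality_reps: int = 200,
    ssd_reps: int = 0,
    correlation_reps: int = 999,
    clock: ClockConfig = ClockConfig(),
    gap_threshold: float = 10.0,
) -> StudyResult:
    """Run every pipeline stage over a multi-population dataset.

    Populations with n < 4 get NaN for the statistics that need n >= 4
    (Tajima's D, mismatch fit); everything else is still computed.
    ssd_reps=0 skips the (expensive) mismatch parametric bootstrap.
    """
    populations = dataset.populations if isinstance(dataset, StudyDataset) else dataset
    if not populations:
        raise ValueError("need at least one population")
    rng = np.random.default_rng(seed)

    rows = []
    t_maxes = []
    for record, aln in populations:
        row: dict = {"locality": record.locality, "n": aln.n}
        for cov in COVARIATES:
            row[cov] = getattr(record, cov)
        div = diversity_summary(aln)
        row.update(h=div.h, sd_h=div.sd_h, p=div.p, pi=div.pi, S=div.S, n_hap=div.n_hap)

        if aln.n >= 4:
            neut = neutrality_summary(aln)
            if math.isfinite(neut.D) or math.isfinite(neut.Fs):
                neut = neutrality_pvalues(neut, reps=neutrality_reps, seed=rng)
            row.update(D=neut.D, p_D=neut.p_D, Fs=neut.Fs, p_Fs=neut.p_Fs)
            spectrum = mismatch_distribution(aln)
            if spectrum.size >= 2:
                fit = fit_sudden_expansion(spectrum, aln.n)
                if ssd_reps:
                    fit = ssd_pvalue(fit, reps=ssd_reps, seed=rng)
                row.update(
                    tau=fit.tau,
                    theta0=fit.theta0,
                    theta1=fit.theta1,
                    ssd=fit.ssd,
                    p_ssd=fit.p_ssd,
                    raggedness=fit.raggedness,
                )
            else:
                row.update(tau=math.nan, ssd=math.nan, raggedness=math.nan)

        raw_tree = clock_tree(aln)
        row["tmrca"] = tmrca_kya(raw_tree, clock)
        row.update(onset_kya=math.nan, t_max_kya=math.nan, r_max=math.nan)
        if raw_tree.tmrca > 0:  # monomorphic samples have no depth to profile
            tree = calibrate(raw_tree, clock)
            traj = classic_skyline(tree, epsilon=0.0)
            if traj.times.size >= 2:
                profile = growth_rate_series(traj)
                growth_onset(profile)
                max_growth(profile)
                row.update(
                    onset_kya=profile.onset_kya,
                    t_max_kya=profile.t_max_kya,
                    r_max=profile.r_max,
                )
                t_maxes.append(profile.t_max_kya)
        rows.append(row)

    frame = pd.DataFrame(rows)
    correlations = correlation_table(frame, reps=correlation_reps, seed=rng)
    finite_t = [t for t in t_maxes if math.isfinite(t)]
    pulses = pulse_histogram(finite_t, gap_threshold=gap_threshold) if finite_t else None
    return StudyResult(
        per_population=frame,
        correlations=correlations,
        pulses=pulses,
        seed=seed,
        parameters={
            "neutrality_reps": neutrality_reps,
            "ssd_reps": ssd_reps,
            "correlation_reps": correlation_reps,
            "divergence_rate": clock.divergence_rate,
            "gap_threshold": gap_threshold,
        },
    )
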