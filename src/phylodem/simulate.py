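"""Coalescent synthetic data with the statistical structure of a lake-fish
mtDNA phylogeography study.

Genealogies are simulated under the standard single-population coalescent
with piecewise-constant (sudden expansion) or exponential size change via
time rescaling; sequences are overlaid with a finite-sites Kimura-style
mutation process (transition bias ``kappa``) or an infinite-sites process
for oracle comparisons.

Units. Coalescent time is measured in units of the *current* population
size, so the scaled diversity theta (= 2uN for mtDNA) converts branch
lengths to mutations: a branch of length ell carries Poisson(ell * theta/2)
mutations, and a sudden expansion at mutational time tau (= 2ut) sits at
coalescent time tau/theta1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genealogy import Genealogy, Node
from .io import Alignment, PopulationRecord

__all__ = [
    "Demography",
    "StudyConfig",
    "StudyDataset",
    "simulate_genealogy",
    "mutate",
    "mutate_infinite_sites",
    "simulate_study",
]

_BASES = np.array(["A", "C", "G", "T"], dtype="U1")
# transition partner (A<->G, C<->T) and the two transversion targets
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass(frozen=True)
class Demography:
    """Single-population demographic model.

    model: 'constant', 'sudden_expansion' or 'exponential'.
    theta0 / theta1: scaled diversity (2uN) before / after the expansion;
    for 'constant' only theta1 is used. tau: expansion time in mutational
    units 2ut. growth_g: exponential growth rate per coalescent time unit
    (size declines as exp(-g t) backward in time).
    """

    model: str = "constant"
    theta1: float = 5.0
    theta0: float = 5.0
    tau: float = 0.0
    growth_g: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("constant", "sudden_expansion", "exponential"):
            raise ValueError(f"unknown demographic model {self.model!r}")
        if self.theta1 <= 0 or self.theta0 <= 0:
            raise ValueError("theta parameters must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.model == "sudden_expansion" and self.theta1 < self.theta0:
            raise ValueError("sudden_expansion requires theta1 >= theta0")

    @property
    def expansion_time_coalescent(self) -> float:
        """Expansion time in coalescent units of the current size."""
        return self.tau / self.theta1

    def relative_size(self, t: float) -> float:
        """Population size at coalescent time t relative to the present size."""
        if self.model == "constant":
            return 1.0
        if self.model == "sudden_expansion":
            return 1.0 if t < self.expansion_time_coalescent else self.theta0 / self.theta1
        return math.exp(-self.growth_g * t)


def _coalescence_waits(n: int, demography: Demography, rng: np.random.Generator):
    """Waiting times between successive coalescences, from k=n down to k=2."""
    t = 0.0
    waits = []
    for k in range(n, 1, -1):
        pairs = k * (k - 1) / 2.0
        if demography.model == "constant":
            w = rng.exponential(1.0 / pairs)
        elif demography.model == "exponential":
            g = demography.growth_g
            e = rng.exponential(1.0)
            if g == 0.0:
                w = e / pairs
            else:
                # invert the cumulative hazard pairs * (e^{g(t+w)} - e^{gt}) / g
                w = math.log(math.exp(g * t) + g * e / pairs) / g - t
        else:  # sudden_expansion: piecewise constant relative size
            t_exp = demography.expansion_time_coalescent
            beta = demography.theta0 / demography.theta1
            e = rng.exponential(1.0)
            if t < t_exp:
                # hazard rate pairs/1 until t_exp, then pairs/beta
                to_break = (t_exp - t) * pairs
                if e <= to_break:
                    w = e / pairs
                else:
                    w = (t_exp - t) + (e - to_break) * beta / pairs
            else:
                w = e * beta / pairs
        waits.append(w)
        t += w
    return waits


def simulate_genealogy(n: int, demography: Demography, seed) -> Genealogy:
    """Simulate a rooted ultrametric coalescent genealogy for ``n`` tips.

    Heights are in coalescent units of the current population size.
    ``seed`` may be an int or a numpy Generator.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    active = [Node(label=f"t{i}", height=0.0) for i in range(n)]
    t = 0.0
    for w in _coalescence_waits(n, demography, rng):
        t += w
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        parent = Node(height=t, children=[active[i], active[j]])
        active[j] = parent
        del active[i]
    return Genealogy(active[0])


# ---------------------------------------------------------------------------
# Mutation overlays
# ---------------------------------------------------------------------------

def mutate(
    genealogy: Genealogy,
    theta: float,
    L: int,
    kappa: float = 4.0,
    seed=None,
) -> Alignment:
    """Finite-sites mutation overlay on a genealogy.

    Per-branch mutation counts are Poisson(branch length * theta / 2),
    target sites uniform over L, substitutions transition-biased with
    transition:transversion parameter kappa (each transversion has weight 1,
    the transition has weight kappa). The root sequence is uniform over bases.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    root_seq = rng.choice(_BASES, size=L)
    p_transition = kappa / (kappa + 2.0)

    ids: list[str] = []
    seqs: list[str] = []

    def descend(node: Node, seq: np.ndarray) -> None:
        if node.is_leaf:
            ids.append(node.label)
            seqs.append("".join(seq))
            return
        for child in node.children:
            length = node.height - child.height
            child_seq = seq.copy()
            n_mut = rng.poisson(length * theta / 2.0)
            for _ in range(n_mut):
                site = rng.integers(L)
                base = child_seq[site]
                if rng.random() < p_transition:
                    child_seq[site] = _TRANSITION[base]
                else:
                    child_seq[site] = _TRANSVERSIONS[base][rng.integers(2)]
            descend(child, child_seq)

    descend(genealogy.root, root_seq)
    return Alignment(ids=tuple(ids), seqs=tuple(seqs))


def mutate_infinite_sites(genealogy: Genealogy, theta: float, seed=None):
    """Infinite-sites overlay; every mutation hits a fresh site.

    Returns (tip_labels, genotypes) where genotypes is an (n, S) 0/1 array
    with one column per mutation (columns in simulation order).
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    tip_labels: list[str] = []
    tip_mutations: list[list[int]] = []
    counter = [0]

    def descend(node: Node, carried: list[int]) -> None:
        if node.is_leaf:
            tip_labels.append(node.label)
            tip_mutations.append(carried)
            return
        for child in node.children:
            length = node.height - child.height
            n_mut = int(rng.poisson(length * theta / 2.0))
            new = list(range(counter[0], counter[0] + n_mut))
            counter[0] += n_mut
            descend(child, carried + new)

    descend(genealogy.root, [])
    S = counter[0]
    geno = np.zeros((len(tip_labels), S), dtype=np.int8)
    for i, muts in enumerate(tip_mutations):
        geno[i, muts] = 1
    return tip_labels, geno


# ---------------------------------------------------------------------------
# Whole-study generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Design of a synthetic multi-population study.

    Mirrors the sampling design of a plateau-wide lake survey: P populations,
    per-population sample sizes in ``n_range``, 1140 bp sequences, a
    monotone west-to-east precipitation gradient over ``precip_range`` mm/yr,
    a log-log link theta_i = exp(a + b log precip_i), and a mix of constant
    and sudden-expansion demographies.
    """

    n_populations: int = 24
    n_range: tuple[int, int] = (7, 162)
    length: int = 1140
    kappa: float = 4.0
    precip_range: tuple[float, float] = (61.0, 487.0)
    link_intercept: float = -4.6
    link_slope: float = 1.0
    expansion_fraction: float = 0.6
    tau: float = 3.0
    theta_ratio: float = 0.05  # theta0 / theta1 for expanding populations

    def __post_init__(self) -> None:
        if self.n_populations < 2:
            raise ValueError("need at least 2 populations")
        if not math.isfinite(self.link_slope):
            raise ValueError("invalid link slope")
        if not (0.0 <= self.expansion_fraction <= 1.0):
            raise ValueError("expansion_fraction must be in [0, 1]")


@dataclass
class StudyDataset:
    """Synthetic study: per-population metadata + alignments + ground truth."""

    populations: list[tuple[PopulationRecord, Alignment]]
    truth: dict
    seed: int


def simulate_study(config: StudyConfig, seed: int) -> StudyDataset:
    """Generate a full synthetic study dataset.

    Precipitation is drawn on a spatial (longitude) gradient with
    multiplicative noise; per-population diversity follows the log-log link
    theta_i = exp(a + b log precip_i); each population is independently
    assigned a constant or sudden-expansion history.
    """
    rng = np.random.default_rng(seed)
    P = config.n_populations
    lo_p, hi_p = config.precip_range

    # positions along the gradient, shuffled so locality order is not spatial
    positions = rng.permutation(np.linspace(0.0, 1.0, P))
    precip = lo_p + positions * (hi_p - lo_p)
    precip *= np.exp(rng.normal(0.0, 0.08, size=P))  # measurement-scale jitter
    precip = np.clip(precip, 1.0, None)

    theta = np.exp(config.link_intercept + config.link_slope * np.log(precip))
    n_lo, n_hi = config.n_range
    sizes = rng.integers(n_lo, n_hi + 1, size=P)
    expanding = rng.random(P) < config.expansion_fraction

    populations = []
    truth_pops = {}
    for i in range(P):
        name = f"pop{i:02d}"
        if expanding[i]:
            demog = Demography(
                model="sudden_expansion",
                theta1=float(theta[i]),
                theta0=float(theta[i] * config.theta_ratio),
                tau=float(config.tau),
            )
        else:
            demog = Demography(model="constant", theta1=float(theta[i]), theta0=float(theta[i]))
        genealogy = simulate_genealogy(int(sizes[i]), demog, rng)
        aln = mutate(genealogy, demog.theta1, config.length, kappa=config.kappa, seed=rng)
        aln = Alignment(
            ids=tuple(f"{name}_{tip}" for tip in aln.ids),
            seqs=aln.seqs,
        )
        record = PopulationRecord(
            locality=name,
            drainage=name,
            n=int(sizes[i]),
            longitude=float(79.0 + positions[i] * 12.0),
            latitude=float(rng.uniform(29.0, 34.0)),
            altitude=float(rng.uniform(4200.0, 4800.0)),
            lake_area=float(np.exp(rng.uniform(np.log(50.0), np.log(2000.0)))),
            basin_area=float(np.exp(rng.uniform(np.log(900.0), np.log(45000.0)))),
            precipitation=float(precip[i]),
        )
        populations.append((record, aln))
        truth_pops[name] = {
            "theta": float(theta[i]),
            "model": demog.model,
            "theta0": demog.theta0,
            "theta1": demog.theta1,
            "tau": demog.tau,
            "precipitation": float(precip[i]),
        }

    truth = {
        "link_intercept": config.link_intercept,
        "link_slope": config.link_slope,
        "populations": truth_pops,
    }
    return StudyDataset(populations=populations, truth=truth, seed=seed)
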