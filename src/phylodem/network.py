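"""Statistical-parsimony haplotype networks (TCS-style, 95% criterion).

The connection limit is the largest number of mutational steps j for which
the probability that a j-step difference between two sequences is
parsimonious (each differing site hit exactly once, no extra substitutions)
stays at or above ``alpha``. Following the classic statistical-parsimony
argument, the total substitution count M between a pair is given the
neutral-coalescent geometric prior with mean estimated from the observed
divergence, substitutions fall uniformly on the L sites, and

    P(parsimony | j differing sites)
        = P(M = j, all sites distinct) / sum_{m >= j} P(M = m) P(j occupied | m)

with P(j occupied | m) = S2(m, j) L! / ((L-j)! L^m) (S2: Stirling numbers of
the second kind; multiple hits at one site are counted as a single observed
difference). The running minimum over j makes the criterion cumulative.

Networks join haplotype pairs in ascending distance order; a j-step join
inserts j-1 inferred intermediate nodes, joins beyond the limit are refused
(separate components), and tied alternative joins are all retained, so loops
may appear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .diversity import HaplotypeTable

__all__ = ["ParsimonyNetwork", "parsimony_probability", "connection_limit", "build_network"]


def _log_stirling2_rows(max_m: int, k: int) -> np.ndarray:
    """log S2(m, j) for m = 0..max_m, j = 0..k (log space recurrence)."""
    table = np.full((max_m + 1, k + 1), -np.inf)
    table[0, 0] = 0.0
    for m in range(1, max_m + 1):
        top = min(m, k)
        for j in range(1, top + 1):
            a = math.log(j) + table[m - 1, j] if np.isfinite(table[m - 1, j]) else -np.inf
            b = table[m - 1, j - 1]
            table[m, j] = np.logaddexp(a, b)
    return table


def _corrected_theta(j: int, L: int, kappa_model: str) -> float:
    """Expected substitutions separating a pair showing j of L differences."""
    q = j / L
    if kappa_model == "uniform":
        # Jukes-Cantor style multiple-hit correction, capped short of the
        # q = 3/4 divergence ceiling so every j <= L stays evaluable
        q = min(q, 0.74)
        return -0.75 * math.log1p(-4.0 * q / 3.0) * L
    if kappa_model == "observed":
        return float(j)
    raise ValueError("kappa_model must be 'uniform' or 'observed'")


def parsimony_probability(j: int, L: int, kappa_model: str = "uniform", truncation_tol: float = 1e-12) -> float:
    """P(a j-step difference over L sites is parsimonious)."""
    if j == 0:
        return 1.0
    if j > L:
        return 0.0
    theta = max(_corrected_theta(j, L, kappa_model), 1e-12)
    log_ratio = math.log(theta) - math.log1p(theta)  # geometric decay of P(M=m)
    log_falling = float(np.sum(np.log(L - np.arange(j))))  # log L!/(L-j)!

    # adaptively extend the truncation until the tail is negligible
    extra = 40
    while True:
        max_m = j + extra
        s2 = _log_stirling2_rows(max_m, j)
        m = np.arange(j, max_m + 1)
        log_terms = m * log_ratio + s2[j:, j] + log_falling - m * math.log(L)
        peak = log_terms.max()
        terms = np.exp(log_terms - peak)
        total = terms.sum()
        if terms[-1] / total < truncation_tol or extra > 4000:
            return float(terms[0] / total)
        extra *= 2


def connection_limit(L: int, alpha: float = 0.95, kappa_model: str = "uniform") -> int:
    """Largest j whose cumulative parsimony probability is >= alpha."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    cumulative = 1.0
    limit = 0
    for j in range(1, L + 1):
        cumulative = min(cumulative, parsimony_probability(j, L, kappa_model))
        if cumulative < alpha:
            break
        limit = j
    return limit


@dataclass
class ParsimonyNetwork:
    """Haplotype network: observed nodes carry their frequency, inferred
    intermediates carry frequency 0; every edge is one mutational step."""

    graph: nx.Graph
    limit: int
    joins: list[tuple[int, int, int]] = None  # accepted (i, j, steps) joins

    @property
    def observed_nodes(self) -> list:
        return [v for v, d in self.graph.nodes(data=True) if not d["inferred"]]

    @property
    def inferred_nodes(self) -> list:
        return [v for v, d in self.graph.nodes(data=True) if d["inferred"]]

    @property
    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def edge_list(self) -> list[tuple]:
        """(node, node, steps, inferred_flag) rows; steps is always 1."""
        rows = []
        for u, v in sorted(self.graph.edges()):
            flag = self.graph.nodes[u]["inferred"] or self.graph.nodes[v]["inferred"]
            rows.append((u, v, 1, int(flag)))
        return rows


def build_network(table: HaplotypeTable, limit: int) -> ParsimonyNetwork:
    """Build the statistical-parsimony network for a haplotype table.

    Pairs are joined in ascending Hamming distance; all pairs at a given
    distance are judged against the components formed by strictly smaller
    distances (tied alternative connections are therefore all retained,
    possibly as loops). A j-step join inserts j-1 inferred intermediates.
    Distances above ``limit`` are refused.
    """
    g = nx.Graph()
    joins: list[tuple[int, int, int]] = []
    H = table.n_haplotypes
    for i in range(H):
        g.add_node(f"H{i}", inferred=False, frequency=int(table.counts[i]))
    if H == 1:
        return ParsimonyNetwork(graph=g, limit=limit, joins=joins)

    d = table.distance_matrix()
    pairs_by_distance: dict[int, list[tuple[int, int]]] = {}
    for i in range(H):
        for j in range(i + 1, H):
            pairs_by_distance.setdefault(int(d[i, j]), []).append((i, j))

    inferred_counter = 0
    for dist in sorted(pairs_by_distance):
        if dist == 0 or dist > limit:
            continue
        # snapshot of components before any join at this distance level
        comp_id = {}
        for c_idx, comp in enumerate(nx.connected_components(g)):
            for v in comp:
                comp_id[v] = c_idx
        for i, j in pairs_by_distance[dist]:
            if comp_id[f"H{i}"] == comp_id[f"H{j}"]:
                continue
            joins.append((i, j, dist))
            chain = [f"H{i}"]
            for _ in range(dist - 1):
                name = f"m{inferred_counter}"
                inferred_counter += 1
                g.add_node(name, inferred=True, frequency=0)
                chain.append(name)
            chain.append(f"H{j}")
            for u, v in zip(chain[:-1], chain[1:]):
                g.add_edge(u, v)
    return ParsimonyNetwork(graph=g, limit=limit, joins=joins)
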