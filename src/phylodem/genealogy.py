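"""Rooted ultrametric genealogies.

A lightweight binary-tree container shared by the coalescent simulator and
the distance clock tree. Node heights are times above the tips: coalescent
units for simulated genealogies, substitutions/site for clock trees, or
years once calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["Node", "Genealogy"]

_ULTRAMETRIC_TOL = 1e-9


@dataclass
class Node:
    label: str | None = None
    height: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Genealogy:
    """Rooted ultrametric tree with tip labels.

    Invariants: all tips at height 0 (tolerance 1e-9), parent heights
    strictly above children, binary internal nodes.
    """

    root: Node

    def __post_init__(self) -> None:
        for node in self.preorder():
            for child in node.children:
                if node.height < child.height - _ULTRAMETRIC_TOL:
                    raise ValueError("parent height below child height")
        tips = self.tips()
        if any(abs(t.height) > _ULTRAMETRIC_TOL for t in tips):
            raise ValueError("tips must sit at height 0 (ultrametric tree)")

    # -- traversal -----------------------------------------------------
    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def tmrca(self) -> float:
        """Root height in whatever units the tree carries."""
        return self.root.height

    # -- derived quantities -------------------------------------------
    def coalescent_times(self) -> list[float]:
        """Heights of internal nodes, ascending (t_1 <= ... <= t_{n-1})."""
        return sorted(n.height for n in self.preorder() if not n.is_leaf)

    def coalescent_intervals(self) -> list[tuple[int, float]]:
        """(k, width) for each inter-coalescent interval, from the tips up.

        k is the number of extant lineages during the interval; the first
        entry covers [0, t_1) with k = n, the last covers
        [t_{n-2}, t_{n-1}) with k = 2. Zero-width intervals are kept.
        """
        times = self.coalescent_times()
        n = len(times) + 1
        out = []
        prev = 0.0
        for i, t in enumerate(times):
            out.append((n - i, t - prev))
            prev = t
        return out

    def branches(self) -> list[tuple[Node, Node, float]]:
        """(parent, child, length) for every branch."""
        out = []
        for node in self.preorder():
            for child in node.children:
                out.append((node, child, node.height - child.height))
        return out

    def total_branch_length(self) -> float:
        return sum(length for _, _, length in self.branches())

    def external_branch_length(self) -> float:
        return sum(length for _, c, length in self.branches() if c.is_leaf)

    def scaled(self, factor: float) -> "Genealogy":
        """Return a copy with every height multiplied by ``factor``."""

        def copy(node: Node) -> Node:
            return Node(
                label=node.label,
                height=node.height * factor,
                children=[copy(c) for c in node.children],
            )

        return Genealogy(copy(self.root))

    # -- serialization -------------------------------------------------
    def to_newick(self) -> str:
        def render(node: Node, parent_height: float | None) -> str:
            if node.is_leaf:
                core = node.label or ""
            else:
                core = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
            if parent_height is None:
                return core
            return f"{core}:{parent_height - node.height:.12g}"

        return render(self.root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Genealogy":
        tree = dendropy.Tree.get(data=text, schema="newick")
        tree.calc_node_root_distances()
        max_depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())

        def convert(dnode) -> Node:
            depth = dnode.root_distance if dnode.root_distance is not None else 0.0
            height = max_depth - depth
            label = dnode.taxon.label if dnode.taxon is not None else None
            return Node(
                label=label,
                height=height,
                children=[convert(c) for c in dnode.child_nodes()],
            )

        return cls(convert(tree.seed_node))
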