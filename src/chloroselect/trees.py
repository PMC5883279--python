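"""Phylogeny container used by the likelihood machinery.

Trees are parsed with dendropy and flattened to parent/child index arrays.
Under reversible models the root placement is arbitrary (pulley principle),
so a bifurcating root is collapsed into a basal multifurcation: branch
lengths then correspond to the identifiable edges of the unrooted tree.
Foreground branches for branch and branch-site models are tagged by node
label — a taxon name tags its terminal branch, an internal-node label tags
the branch above that node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


@dataclass
class Phylogeny:
    parent: np.ndarray            # per node; -1 at the root
    children: list[list[int]]
    branch_lengths: np.ndarray    # length of the edge above each node; nan at root
    labels: list[str | None]      # leaf taxon names / optional internal labels
    foreground_labels: frozenset[str] = frozenset()
    _postorder: list[int] = field(default_factory=list, repr=False)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, source: str, foreground: set[str] | None = None,
                    is_path: bool | None = None) -> "Phylogeny":
        if is_path is None:
            is_path = "(" not in source
        kwargs = {"path" if is_path else "data": source}
        t = dendropy.Tree.get(schema="newick", suppress_internal_node_taxa=False,
                              preserve_underscores=True, **kwargs)
        t.suppress_unifurcations()
        seed = t.seed_node
        kids = seed.child_nodes()
        if len(kids) == 2 and any(not c.is_leaf() for c in kids):
            # merge the two root edges into one identifiable unrooted edge
            t.collapse_basal_bifurcation()
        return cls._from_dendropy(t, foreground or set())

    @classmethod
    def _from_dendropy(cls, t: dendropy.Tree, foreground: set[str]) -> "Phylogeny":
        nodes = list(t.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        children: list[list[int]] = [[] for _ in nodes]
        bl = np.full(len(nodes), np.nan)
        labels: list[str | None] = [None] * len(nodes)
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                p = index[id(n.parent_node)]
                parent[i] = p
                children[p].append(i)
                bl[i] = n.edge.length if n.edge.length is not None else np.nan
            if n.taxon is not None:
                labels[i] = n.taxon.label
            elif n.label:
                labels[i] = n.label
        tree = cls(parent, children, bl, labels, frozenset(foreground))
        missing = tree.foreground_labels - {l for l in labels if l}
        if missing:
            raise TreeError(f"foreground labels not in tree: {sorted(missing)}")
        return tree

    def __post_init__(self):
        order: list[int] = []

        def visit(i):
            for c in self.children[i]:
                visit(c)
            order.append(i)

        visit(self.root)
        self._postorder = order

    # -- structure --------------------------------------------------------
    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent < 0)[0][0])

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def postorder(self) -> list[int]:
        return self._postorder

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def taxa(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    @property
    def edge_nodes(self) -> np.ndarray:
        """Nodes below an edge, i.e. every node except the root, postorder."""
        return np.array([i for i in self._postorder if self.parent[i] >= 0])

    def edge_name(self, i: int) -> str:
        if self.labels[i]:
            return self.labels[i]
        tips = sorted(self.labels[j] for j in self.subtree_leaves(i))
        return "mrca(" + ",".join(tips[:2]) + ")"

    def subtree_leaves(self, i: int) -> list[int]:
        if self.is_leaf(i):
            return [i]
        out = []
        for c in self.children[i]:
            out.extend(self.subtree_leaves(c))
        return out

    def foreground_mask(self) -> np.ndarray:
        """Per-node flag: the edge above this node is a foreground branch."""
        return np.array([(self.labels[i] in self.foreground_labels)
                         for i in range(self.n_nodes)], dtype=bool)

    def with_foreground(self, foreground: set[str]) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), [list(c) for c in self.children],
                         self.branch_lengths.copy(), list(self.labels),
                         frozenset(foreground))

    def with_branch_lengths(self, bl_by_edge: np.ndarray) -> "Phylogeny":
        """New tree with edge lengths given in ``edge_nodes`` order."""
        bl = np.full(self.n_nodes, np.nan)
        bl[self.edge_nodes] = bl_by_edge
        return Phylogeny(self.parent.copy(), [list(c) for c in self.children],
                         bl, list(self.labels), self.foreground_labels)

    def edge_lengths(self, default: float = 0.1) -> np.ndarray:
        """Edge lengths in ``edge_nodes`` order, NaN replaced by ``default``."""
        bl = self.branch_lengths[self.edge_nodes]
        return np.where(np.isfinite(bl), bl, default)

    def parent_of_taxon(self, taxon: str) -> int:
        for i in self.leaves:
            if self.labels[i] == taxon:
                return int(self.parent[i])
        raise TreeError(f"taxon {taxon!r} not in tree")

    def leaf_index(self, taxon: str) -> int:
        for i in self.leaves:
            if self.labels[i] == taxon:
                return i
        raise TreeError(f"taxon {taxon!r} not in tree")

    # -- output -----------------------------------------------------------
    def to_newick(self) -> str:
        def rec(i):
            bl = self.branch_lengths[i]
            suffix = "" if not np.isfinite(bl) else f":{bl:.6f}"
            if self.is_leaf(i):
                return f"{self.labels[i]}{suffix}"
            inner = ",".join(rec(c) for c in self.children[i])
            lab = self.labels[i] or ""
            return f"({inner}){lab}{suffix}"

        return rec(self.root) + ";"


def validate_tree_against_alignment(tree: Phylogeny, taxa: list[str]) -> None:
    t_taxa, a_taxa = set(tree.taxa), set(taxa)
    if t_taxa != a_taxa:
        raise TreeError(
            f"tree/alignment taxon mismatch: only-in-tree={sorted(t_taxa - a_taxa)}, "
            f"only-in-alignment={sorted(a_taxa - t_taxa)}")
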