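"""Rooted phylogeny container with array-based traversal.

The tree is stored as flat arrays (parent pointers, edge lengths) with tips
occupying indices ``0 .. n_tips-1``.  Newick parsing is delegated to
:mod:`dendropy`; everything numerical (depths, covariance, pruning orders)
is computed directly on the arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "NotUltrametricWarning",
    "normalize_label",
]

#: relative tolerance (x root age) used by the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6


class NotUltrametricWarning(UserWarning):
    """Tip depths differ by more than the tolerance."""


def normalize_label(label: str) -> str:
    """Normalize a species label: strip and unify spaces/underscores."""
    return label.strip().replace(" ", "_")


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths in Myr.

    Attributes
    ----------
    parent : ndarray of int, shape (n_nodes,)
        Parent index per node; -1 for the root.
    edge_length : ndarray of float, shape (n_nodes,)
        Length of the edge subtending each node; 0 for the root.
    labels : list of str or None
        Tip labels for nodes ``0..n_tips-1``; None for internal nodes.
    n_tips : int
        Number of tips.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    labels: list
    n_tips: int
    children: list = field(default=None, repr=False)
    _postorder: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.edge_length = np.asarray(self.edge_length, dtype=np.float64)
        n = len(self.parent)
        if self.children is None:
            ch = [[] for _ in range(n)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self.children = ch
        if self._postorder is None:
            self._postorder = self._compute_postorder()

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tip_labels(self) -> list:
        return list(self.labels[: self.n_tips])

    def _compute_postorder(self) -> np.ndarray:
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return np.array(order[::-1], dtype=np.int64)

    @property
    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        return self._postorder

    @property
    def preorder(self) -> np.ndarray:
        return self._postorder[::-1]

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for node in self.preorder:
            p = self.parent[node]
            if p >= 0:
                depth[node] = depth[p] + self.edge_length[node]
        return depth

    @property
    def root_age(self) -> float:
        """Maximum root-to-tip distance (tree height, Myr)."""
        return float(self.node_depths()[: self.n_tips].max())

    def node_ages(self) -> np.ndarray:
        """Time before present of every node (present = deepest tip)."""
        d = self.node_depths()
        return d[: self.n_tips].max() - d

    @property
    def total_tree_length(self) -> float:
        """Sum of all branch lengths."""
        mask = self.parent >= 0
        return float(self.edge_length[mask].sum())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.node_depths()[: self.n_tips]
        return float(d.max() - d.min()) <= rtol * max(d.max(), 1e-300)

    # ------------------------------------------------------------ covariance
    def vcv(self) -> np.ndarray:
        """Brownian-motion covariance: shared root-to-MRCA path lengths.

        Rows/columns follow tip index order (= ``tip_labels`` order).
        """
        depth = self.node_depths()
        n = self.n_tips
        C = np.zeros((n, n))
        tipsets = [None] * self.n_nodes
        for node in self.postorder:
            if node < n:
                tipsets[node] = [node]
                C[node, node] = depth[node]
            else:
                kids = self.children[node]
                acc = []
                for k in kids:
                    tk = tipsets[k]
                    for prev in acc:
                        C[np.ix_(prev, tk)] = depth[node]
                        C[np.ix_(tk, prev)] = depth[node]
                    acc.append(tk)
                merged = [t for ts in acc for t in ts]
                tipsets[node] = merged
        return C

    # ---------------------------------------------------------------- newick
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        dtree = dtree.clone(depth=1)
        # collapse root unifurcations left by pruning
        seed = dtree.seed_node
        while len(seed.child_nodes()) == 1:
            child = seed.child_nodes()[0]
            child.parent_node = None
            child.edge.length = None
            dtree.seed_node = child
            seed = child
        leaves = [lf for lf in dtree.leaf_node_iter()]
        internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
        n_tips = len(leaves)
        nodes = leaves + internals
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        elen = np.zeros(len(nodes))
        labels = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                elen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                lab = nd.taxon.label if nd.taxon is not None else nd.label
                labels[i] = normalize_label(str(lab))
        return cls(parent=parent, edge_length=elen, labels=labels, n_tips=n_tips)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises its own error hierarchy
            if "uplicate" in str(exc):
                raise ValueError(f"duplicate tip labels: {exc}") from exc
            raise
        return cls.from_dendropy(dtree)

    def to_newick(self) -> str:
        """Serialize to a plain Newick string with full float precision."""
        parts = [None] * self.n_nodes
        for node in self.postorder:
            if node < self.n_tips:
                s = self.labels[node]
            else:
                s = "(" + ",".join(parts[k] for k in self.children[node]) + ")"
            if self.parent[node] >= 0:
                s += ":" + repr(float(self.edge_length[node]))
            parts[node] = s
        return parts[self.root] + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ----------------------------------------------------------------- prune
    def prune_to(self, keep_labels) -> "Phylogeny":
        """Return the subtree induced by ``keep_labels`` (tip labels)."""
        keep = {normalize_label(l) for l in keep_labels}
        present = [l for l in self.tip_labels if l in keep]
        if not present:
            raise ValueError("no requested tip labels present in tree")
        if len(present) == self.n_tips:
            return self
        dtree = dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )
        dtree.retain_taxa_with_labels(present)
        return Phylogeny.from_dendropy(dtree)

    # ------------------------------------------------------------ validation
    def validate(self, warn_ultrametric: bool = True) -> None:
        labs = self.tip_labels
        if len(set(labs)) != len(labs):
            dupes = sorted({l for l in labs if labs.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        mask = self.parent >= 0
        if np.any(self.edge_length[mask] <= 0):
            raise ValueError("all branch lengths must be > 0")
        if warn_ultrametric and not self.is_ultrametric():
            warnings.warn(
                "tree is not ultrametric within tolerance; "
                "time-binned summaries use depths as-is",
                NotUltrametricWarning,
                stacklevel=2,
            )
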