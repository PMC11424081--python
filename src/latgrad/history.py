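"""Piecewise-constant discrete-state histories painted on a tree.

A :class:`BranchHistory` records, for every non-root node, the ordered state
segments of the edge leading to it (from the parent end to the node), plus
the state at every node.  It is used both for forward CTMC simulations and
for stochastic character maps sampled conditional on tip data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo import Phylogeny

__all__ = ["BranchHistory"]


@dataclass
class BranchHistory:
    """States along every edge of a tree.

    Attributes
    ----------
    tree : Phylogeny
    segments : dict
        ``node -> [(duration, state), ...]`` ordered from the parent end of
        the edge down to the node.  Durations sum to the edge length.
    node_states : ndarray of int
        State at each node (the end of its subtending edge; root included).
    n_changes : int
        Total number of state changes across all edges.
    """

    tree: Phylogeny
    segments: dict
    node_states: np.ndarray
    n_changes: int

    def __post_init__(self):
        self.node_states = np.asarray(self.node_states, dtype=np.int64)

    @property
    def tip_states(self) -> np.ndarray:
        return self.node_states[: self.tree.n_tips]

    def validate(self, atol: float = 1e-9) -> None:
        """Check segment contiguity and endpoint consistency."""
        tree = self.tree
        for node in tree.postorder:
            p = tree.parent[node]
            if p < 0:
                continue
            segs = self.segments[node]
            total = sum(d for d, _ in segs)
            if abs(total - tree.edge_length[node]) > atol * max(1.0, tree.edge_length[node]):
                raise ValueError(f"segments of edge {node} do not span the edge")
            if segs[0][1] != self.node_states[p]:
                raise ValueError(f"edge {node} does not start in its parent's state")
            if segs[-1][1] != self.node_states[node]:
                raise ValueError(f"edge {node} does not end in the node's state")

    def effective_edge_lengths(self, weights) -> np.ndarray:
        """Per-edge sum of ``weights[state] * duration`` over segments.

        Returns an array indexed by node (0 at the root).  ``weights`` is
        indexed by state as stored in the history.
        """
        weights = np.asarray(weights, dtype=float)
        out = np.zeros(self.tree.n_nodes)
        for node, segs in self.segments.items():
            out[node] = sum(d * weights[s] for d, s in segs)
        return out

    def state_occupancy(self, n_states: int, ages: np.ndarray, bin_width: float,
                        n_bins: int, observed_of=None) -> np.ndarray:
        """Lineage-time per (time bin, observed state).

        Bins are measured backward from the present: bin k covers ages
        ``[k*w, (k+1)*w)``.  ``observed_of`` maps stored states to observed
        states (identity by default); hidden classes are collapsed with it.
        """
        occ = np.zeros((n_bins, n_states))
        tree = self.tree
        for node, segs in self.segments.items():
            age_hi = ages[tree.parent[node]]
            t = 0.0
            for dur, state in segs:
                a1 = age_hi - t          # older end of segment
                a0 = age_hi - t - dur    # younger end
                s = state if observed_of is None else observed_of(state)
                k0 = max(int(np.floor(a0 / bin_width)), 0)
                k1 = min(int(np.ceil(a1 / bin_width)), n_bins)
                for k in range(k0, k1):
                    lo, hi = k * bin_width, (k + 1) * bin_width
                    overlap = min(a1, hi) - max(a0, lo)
                    if overlap > 0:
                        occ[k, s] += overlap
                t += dur
        return occ

    def to_simmap_newick(self, state_names=None, observed_of=None) -> str:
        """Serialize as simmap-extended Newick (``{state,time:...}`` edges)."""
        tree = self.tree
        if state_names is None:
            n_states = int(self.node_states.max()) + 1
            state_names = [str(i) for i in range(n_states)]

        def edge_annot(node):
            parts = []
            for dur, state in self.segments[node]:
                s = state if observed_of is None else observed_of(state)
                parts.append(f"{state_names[s]},{dur:.10g}")
            return "{" + ":".join(parts) + "}"

        built = [None] * tree.n_nodes
        for node in tree.postorder:
            if node < tree.n_tips:
                s = tree.labels[node]
            else:
                s = "(" + ",".join(built[k] for k in tree.children[node]) + ")"
            if tree.parent[node] >= 0:
                s += ":" + edge_annot(node)
            built[node] = s
        return built[tree.root] + ";"
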