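"""Synthetic data generators.

Everything the analysis pipeline consumes can be simulated here: ultrametric
birth-death trees, discrete CTMC histories, state-dependent multivariate
Brownian traits with lognormal background rate variation, allometric raw
measurements, and cell-by-species occurrence tables.  All generators are
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .history import BranchHistory
from .phylo import Phylogeny

__all__ = [
    "SimConfig",
    "TrueHistory",
    "simulate_bd_tree",
    "simulate_mk_history",
    "simulate_traits_sdbm",
    "simulate_allometric_traits",
    "simulate_occurrence_table",
]

#: degrees of latitude per 150-km grid band
_CELL_DEG = 1.35


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimConfig:
    """Bundle of simulation parameters (see module functions for semantics)."""

    n_tips: int = 64
    birth_rate: float = 1.0
    death_rate: float = 0.0
    q_matrix: np.ndarray = None
    root_freq: np.ndarray = None
    state_rate_multipliers: np.ndarray = None
    background_sigma2: np.ndarray = None
    ucln_sd: float = 0.0
    allometric_slopes: np.ndarray = None
    seed: int = 0

    def __post_init__(self):
        if self.q_matrix is None:
            q = np.full((4, 4), 0.1)
            np.fill_diagonal(q, -0.3)
            self.q_matrix = q
        self.q_matrix = np.asarray(self.q_matrix, dtype=float)
        k = self.q_matrix.shape[0]
        if self.root_freq is None:
            self.root_freq = np.full(k, 1.0 / k)
        if self.state_rate_multipliers is None:
            self.state_rate_multipliers = np.ones(k)
        if self.background_sigma2 is None:
            self.background_sigma2 = np.ones(8)
        if self.allometric_slopes is None:
            self.allometric_slopes = np.ones(len(self.background_sigma2))
        self.validate()

    def validate(self):
        if not (self.birth_rate > self.death_rate >= 0):
            raise ValueError("require birth_rate > death_rate >= 0")
        q = self.q_matrix
        if np.any(q - np.diag(np.diag(q)) < 0):
            raise ValueError("off-diagonal CTMC rates must be >= 0")
        if np.max(np.abs(q.sum(axis=1))) > 1e-8 * max(np.abs(q).max(), 1.0):
            raise ValueError("CTMC generator rows must sum to 0")
        if np.any(np.asarray(self.state_rate_multipliers) <= 0):
            raise ValueError("state rate multipliers must be > 0")


@dataclass
class TrueHistory:
    """Ground truth of a full simulation round."""

    history: BranchHistory
    branch_rates: np.ndarray = None
    tip_traits: pd.DataFrame = None

    @property
    def tip_states(self):
        return self.history.tip_states


# ------------------------------------------------------------------ BD trees
class _Lin:
    __slots__ = ("t_start", "t_end", "children", "extinct")

    def __init__(self, t_start):
        self.t_start = t_start
        self.t_end = None
        self.children = []
        self.extinct = False


def _bd_attempt(n_tips, birth, death, rng):
    root = _Lin(0.0)
    a, b = _Lin(0.0), _Lin(0.0)
    root.children = [a, b]
    root.t_end = 0.0
    alive = [a, b]
    t = 0.0
    total = birth + death
    while True:
        k = len(alive)
        if k == 0:
            return None
        if k == n_tips:
            # stop just before the next event so the final inter-event
            # interval is included (Yule root age E = sum_{k=2..n} 1/(k*lambda))
            t += rng.exponential(1.0 / (k * total))
            for lin in alive:
                lin.t_end = t
            return root
        t += rng.exponential(1.0 / (k * total))
        i = rng.integers(k)
        lin = alive.pop(i)
        lin.t_end = t
        if rng.random() < birth / total:
            c1, c2 = _Lin(t), _Lin(t)
            lin.children = [c1, c2]
            alive.extend([c1, c2])
        else:
            lin.extinct = True


def _prune_extinct(node):
    """Drop extinct subtrees; returns node or None, collapsing unifurcations."""
    if not node.children:
        return None if node.extinct else node
    kept = [c for c in (_prune_extinct(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]  # t_start stays: edge length computed from parent below
    node.children = kept
    return node


def simulate_bd_tree(n_tips, birth_rate, death_rate=0.0, seed=None) -> Phylogeny:
    """Forward birth-death tree with exactly ``n_tips`` extant tips.

    Simulation restarts on extinction (conditioning on survival); extinct
    side branches are pruned, so the result is ultrametric.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    if not (birth_rate > death_rate >= 0):
        raise ValueError("require birth_rate > death_rate >= 0")
    rng = _as_rng(seed)
    while True:
        root = _bd_attempt(n_tips, birth_rate, death_rate, rng)
        if root is None:
            continue
        root = _prune_extinct(root)
        # count surviving tips (death can prune below n only via restart above,
        # but a root-side collapse keeps all n survivors)
        tips = []
        stack = [root]
        while stack:
            nd = stack.pop()
            if nd.children:
                stack.extend(nd.children)
            else:
                tips.append(nd)
        if len(tips) == n_tips:
            break
    # assemble arrays: tips first (stable traversal order), then internals
    internals = []
    order_tips = []
    stack = [root]
    while stack:
        nd = stack.pop()
        if nd.children:
            internals.append(nd)
            stack.extend(reversed(nd.children))
        else:
            order_tips.append(nd)
    nodes = order_tips + internals
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    elen = np.zeros(len(nodes))
    t0 = root.t_start
    for nd in internals:
        for c in nd.children:
            parent[idx[id(c)]] = idx[id(nd)]
            elen[idx[id(c)]] = c.t_end - nd.t_end
    _ = t0
    labels = [f"t{i + 1}" for i in range(len(order_tips))] + [None] * len(internals)
    return Phylogeny(parent=parent, edge_length=elen, labels=labels,
                     n_tips=len(order_tips))


# ------------------------------------------------------------- CTMC history
def simulate_mk_history(tree: Phylogeny, q_matrix, root_freq=None,
                        seed=None) -> BranchHistory:
    """Exact forward CTMC realization (exponential waiting times) on a tree."""
    rng = _as_rng(seed)
    Q = np.asarray(q_matrix, dtype=float)
    k = Q.shape[0]
    if root_freq is None:
        root_freq = np.full(k, 1.0 / k)
    root_freq = np.asarray(root_freq, dtype=float)
    node_states = np.zeros(tree.n_nodes, dtype=np.int64)
    segments = {}
    n_changes = 0
    root = tree.root
    node_states[root] = rng.choice(k, p=root_freq / root_freq.sum())
    for node in tree.preorder:
        p = tree.parent[node]
        if p < 0:
            continue
        state = node_states[p]
        L = tree.edge_length[node]
        t = 0.0
        segs = []
        while True:
            rate = -Q[state, state]
            dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if t + dt >= L:
                segs.append((L - t, int(state)))
                break
            segs.append((dt, int(state)))
            t += dt
            probs = Q[state].clip(min=0.0)
            probs[state] = 0.0
            state = rng.choice(k, p=probs / probs.sum())
            n_changes += 1
        node_states[node] = state
        segments[node] = segs
    return BranchHistory(tree=tree, segments=segments,
                         node_states=node_states, n_changes=n_changes)


# ------------------------------------------- state-dependent Brownian traits
def simulate_traits_sdbm(tree: Phylogeny, history: BranchHistory, base_sigma2,
                         multipliers, ucln_sd=0.0, seed=None, root_value=None):
    """Tip traits under state-dependent BM with UCLN background rates.

    Each edge gets an i.i.d. lognormal background rate (median 1, SD of the
    log = ``ucln_sd``); trait-j increments on an edge are Normal with
    variance ``base_sigma2[j] * rate * sum_seg multipliers[state] * dur``.

    Returns ``(tip_traits DataFrame, branch_rates array indexed by node)``.
    """
    rng = _as_rng(seed)
    base_sigma2 = np.atleast_1d(np.asarray(base_sigma2, dtype=float))
    multipliers = np.asarray(multipliers, dtype=float)
    p = len(base_sigma2)
    if root_value is None:
        root_value = np.zeros(p)
    branch_rates = np.ones(tree.n_nodes)
    has_edge = tree.parent >= 0
    if ucln_sd > 0:
        branch_rates[has_edge] = np.exp(rng.normal(0.0, ucln_sd, has_edge.sum()))
    eff = history.effective_edge_lengths(multipliers)
    values = np.zeros((tree.n_nodes, p))
    values[tree.root] = root_value
    for node in tree.preorder:
        par = tree.parent[node]
        if par < 0:
            continue
        var = base_sigma2 * branch_rates[node] * eff[node]
        values[node] = values[par] + rng.normal(0.0, 1.0, p) * np.sqrt(var)
    cols = [f"trait_{j + 1}" for j in range(p)]
    tip_traits = pd.DataFrame(values[: tree.n_tips], index=tree.tip_labels,
                              columns=cols)
    tip_traits.index.name = "species"
    return tip_traits, branch_rates


def _bm_on_tree(tree: Phylogeny, sigma2, p, rng):
    """Plain BM tip values, one column per trait, root at 0."""
    sigma2 = np.broadcast_to(np.atleast_1d(np.asarray(sigma2, float)), (p,))
    values = np.zeros((tree.n_nodes, p))
    for node in tree.preorder:
        par = tree.parent[node]
        if par < 0:
            continue
        sd = np.sqrt(sigma2 * tree.edge_length[node])
        values[node] = values[par] + rng.normal(0.0, 1.0, p) * sd
    return values[: tree.n_tips]


def simulate_allometric_traits(tree: Phylogeny, sizes, slopes, noise_sigma2,
                               seed=None) -> pd.DataFrame:
    """Raw positive traits: log trait = slope * log size + BM noise on tree."""
    rng = _as_rng(seed)
    sizes = np.asarray(
        sizes.loc[tree.tip_labels] if isinstance(sizes, pd.Series) else sizes,
        dtype=float,
    )
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    slopes = np.atleast_1d(np.asarray(slopes, dtype=float))
    p = len(slopes)
    noise = (
        _bm_on_tree(tree, noise_sigma2, p, rng)
        if np.any(np.atleast_1d(noise_sigma2) > 0)
        else np.zeros((tree.n_tips, p))
    )
    log_traits = np.log(sizes)[:, None] * slopes[None, :] + noise
    cols = [f"trait_{j + 1}" for j in range(p)]
    out = pd.DataFrame(np.exp(log_traits), index=tree.tip_labels, columns=cols)
    out.index.name = "species"
    return out


# ------------------------------------------------------------ occurrence grid
def simulate_occurrence_table(table: pd.DataFrame, cells_per_species=1,
                              latitudinal_spread=0.0, seed=None,
                              n_lon_cells=240) -> pd.DataFrame:
    """Cell-by-species occurrence rows on an abstract 150-km-like grid.

    Each species occupies ``cells_per_species`` cells (distinct longitude
    bands) whose latitudes lie within ``latitudinal_spread`` degrees of its
    range centroid.  Columns: cell, species, cell_lat.
    """
    rng = _as_rng(seed)
    rows = []
    for _, rec in table.iterrows():
        lons = rng.choice(n_lon_cells, size=cells_per_species, replace=False)
        for lon in np.sort(lons):
            lat = rec["lat_centroid"]
            if latitudinal_spread > 0:
                lat = lat + rng.uniform(-latitudinal_spread, latitudinal_spread)
            lat = float(np.clip(lat, -90.0, 90.0))
            band = int(np.floor((lat + 90.0) / _CELL_DEG))
            cell_lat = band * _CELL_DEG - 90.0 + _CELL_DEG / 2.0
            rows.append((f"c{band}_{int(lon)}", rec["species"], cell_lat))
    return pd.DataFrame(rows, columns=["cell", "species", "cell_lat"])
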