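"""Mk models with hidden rate classes, stochastic mapping, and occupancy.

The observed character has ``n_observed`` states (4 latitude quartiles by
default).  Hidden rate classes expand the state space to
``n_observed * n_classes``: observed-state transitions happen only within a
class, and class switches (one shared rate) preserve the observed state.
Likelihoods use Felsenstein pruning with matrix exponentials; stochastic
maps are exact posterior draws via backward sampling plus endpoint-
conditioned uniformization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.special import gammaln

from .history import BranchHistory
from .phylo import Phylogeny

__all__ = [
    "MkModel",
    "FittedMk",
    "build_mk_generator",
    "mk_loglik",
    "marginal_ancestral_probs",
    "joint_ancestral_states",
    "fit_mk_models",
    "aicc",
    "akaike_weights",
    "sample_stochastic_maps",
    "occupancy_through_time",
]

#: documented order of the 12 ARD rates for a 4-state character:
#: row-major over ordered pairs (from, to), diagonal excluded.
ARD_PAIRS = [(i, j) for i in range(4) for j in range(4) if i != j]


# ---------------------------------------------------------------- model spec
@dataclass
class MkModel:
    """Mk generator with optional hidden rate classes.

    ``within_rates`` has shape (n_classes,) for ER tying or (n_classes, 12)
    for ARD; ``switch_rate`` is the single shared class-switch rate (ignored
    when n_classes == 1).
    """

    tying: str
    n_classes: int
    within_rates: np.ndarray
    switch_rate: float = 0.0
    n_observed: int = 4
    root: str = "flat"

    def __post_init__(self):
        if self.tying not in ("ER", "ARD"):
            raise ValueError("tying must be 'ER' or 'ARD'")
        self.within_rates = np.atleast_1d(np.asarray(self.within_rates, float))
        if self.tying == "ARD":
            self.within_rates = self.within_rates.reshape(self.n_classes, -1)
        if np.any(self.within_rates < 0) or self.switch_rate < 0:
            raise ValueError("rates must be >= 0")

    @property
    def n_states(self) -> int:
        return self.n_observed * self.n_classes

    @property
    def n_params(self) -> int:
        base = self.n_classes if self.tying == "ER" else self.within_rates.size
        return base + (1 if self.n_classes > 1 else 0)

    def observed_of(self, state: int) -> int:
        return state % self.n_observed

    @property
    def Q(self) -> np.ndarray:
        m, c = self.n_observed, self.n_classes
        K = m * c
        Q = np.zeros((K, K))
        n_pairs = m * (m - 1)
        pairs = [(i, j) for i in range(m) for j in range(m) if i != j]
        for cl in range(c):
            off = cl * m
            if self.tying == "ER":
                rate = self.within_rates[cl]
                for i, j in pairs:
                    Q[off + i, off + j] = rate
            else:
                for r, (i, j) in enumerate(pairs[:n_pairs]):
                    Q[off + i, off + j] = self.within_rates[cl, r]
        if c > 1:
            for cl in range(c):
                for cl2 in range(c):
                    if cl2 == cl:
                        continue
                    for s in range(m):
                        Q[cl * m + s, cl2 * m + s] = self.switch_rate
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def root_prior(self) -> np.ndarray:
        K = self.n_states
        if self.root == "flat":
            return np.full(K, 1.0 / K)
        if self.root == "stationary":
            Q = self.Q
            A = np.vstack([Q.T, np.ones(K)])
            b = np.zeros(K + 1)
            b[-1] = 1.0
            pi, *_ = np.linalg.lstsq(A, b, rcond=None)
            return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()
        raise ValueError(f"unknown root treatment {self.root!r}")


def build_mk_generator(tying, n_classes, params, n_observed=4,
                       root="flat") -> MkModel:
    """Assemble an MkModel from a parameter spec.

    ``params`` is either a dict with keys ``within`` (and ``switch`` when
    n_classes > 1) or a flat array ordered (within rates ..., switch).
    """
    if isinstance(params, dict):
        within = np.asarray(params["within"], dtype=float)
        switch = float(params.get("switch", 0.0))
    else:
        flat = np.atleast_1d(np.asarray(params, dtype=float))
        n_within = n_classes if tying == "ER" else n_classes * n_observed * (n_observed - 1)
        within = flat[:n_within]
        switch = float(flat[n_within]) if n_classes > 1 else 0.0
    return MkModel(tying=tying, n_classes=n_classes, within_rates=within,
                   switch_rate=switch, n_observed=n_observed, root=root)


# ------------------------------------------------------------ transition P(t)
class TransitionKernel:
    """P(t) = expm(Q t), via eigendecomposition with an expm fallback."""

    def __init__(self, Q, check_t=1.0):
        self.Q = np.asarray(Q, dtype=float)
        self._use_eig = False
        try:
            w, V = np.linalg.eig(self.Q)
            Vi = np.linalg.inv(V)
            P_eig = (V * np.exp(w * check_t)) @ Vi
            if np.max(np.abs(P_eig.imag)) < 1e-9 and np.max(
                np.abs(P_eig.real - expm(self.Q * check_t))
            ) < 1e-9:
                self._w, self._V, self._Vi = w, V, Vi
                self._use_eig = True
        except np.linalg.LinAlgError:
            pass
        self._cache = {}

    def __call__(self, t: float) -> np.ndarray:
        P = self._cache.get(t)
        if P is None:
            if self._use_eig:
                P = ((self._V * np.exp(self._w * t)) @ self._Vi).real
            else:
                P = expm(self.Q * t)
            np.clip(P, 0.0, None, out=P)
            self._cache[t] = P
        return P


def _tip_partials(tree: Phylogeny, tip_states, model: MkModel) -> np.ndarray:
    tip_states = np.asarray(tip_states, dtype=np.int64)
    if len(tip_states) != tree.n_tips:
        raise ValueError("one observed state per tip required")
    if np.any((tip_states < 0) | (tip_states >= model.n_observed)):
        raise ValueError("tip states out of range")
    K = model.n_states
    partial = np.zeros((tree.n_nodes, K))
    for tip in range(tree.n_tips):
        for cl in range(model.n_classes):
            partial[tip, cl * model.n_observed + tip_states[tip]] = 1.0
    return partial


def _pruning(tree: Phylogeny, tip_states, model: MkModel,
             kernel: TransitionKernel = None):
    """Scaled pruning pass.

    Returns (partial, log_scale, kernel): ``partial[node]`` are conditional
    likelihoods of the subtree given the node's state, rescaled to max 1;
    ``log_scale`` is the summed log of the rescaling factors.
    """
    if kernel is None:
        kernel = TransitionKernel(model.Q, check_t=max(tree.edge_length.max(), 1e-3))
    partial = _tip_partials(tree, tip_states, model)
    log_scale = 0.0
    for node in tree.postorder:
        if node < tree.n_tips:
            continue
        prod = np.ones(model.n_states)
        for child in tree.children[node]:
            P = kernel(tree.edge_length[child])
            prod *= P @ partial[child]
        mx = prod.max()
        if mx <= 0.0:
            return None, -np.inf, kernel
        partial[node] = prod / mx
        log_scale += np.log(mx)
    return partial, log_scale, kernel


def mk_loglik(tree: Phylogeny, tip_states, model: MkModel) -> float:
    """Felsenstein pruning log-likelihood; -inf for impossible data."""
    partial, log_scale, _ = _pruning(tree, tip_states, model)
    if partial is None:
        return -np.inf
    lik = float(model.root_prior() @ partial[tree.root])
    if lik <= 0.0:
        return -np.inf
    return np.log(lik) + log_scale


# --------------------------------------------------- marginals / joint states
def marginal_ancestral_probs(tree: Phylogeny, tip_states, model: MkModel):
    """Marginal posterior state probabilities at every node (up-down pass).

    Returns an (n_nodes, n_states) array over expanded states.
    """
    partial, log_scale, kernel = _pruning(tree, tip_states, model)
    if partial is None:
        raise ValueError("data impossible under model")
    K = model.n_states
    down = np.zeros((tree.n_nodes, K))
    down[tree.root] = model.root_prior()
    for node in tree.preorder:
        for child in tree.children[node]:
            # outside message excluding this child's subtree
            out = down[node].copy()
            for sib in tree.children[node]:
                if sib == child:
                    continue
                out *= kernel(tree.edge_length[sib]) @ partial[sib]
            msg = out @ kernel(tree.edge_length[child])
            mx = msg.max()
            down[child] = msg / mx if mx > 0 else msg
    post = down * partial
    post /= post.sum(axis=1, keepdims=True)
    return post


def joint_ancestral_states(tree: Phylogeny, tip_states, model: MkModel):
    """Jointly most probable state assignment (max-product on the tree).

    Ties are broken toward the lowest expanded-state index.  Returns
    ``(observed_states, expanded_states)`` arrays over all nodes.
    """
    kernel = TransitionKernel(model.Q, check_t=max(tree.edge_length.max(), 1e-3))
    K = model.n_states
    with np.errstate(divide="ignore"):
        logtip = np.log(_tip_partials(tree, tip_states, model))
    L = np.zeros((tree.n_nodes, K))
    back = {}
    for node in tree.postorder:
        if node < tree.n_tips:
            L[node] = logtip[node]
            continue
        for child in tree.children[node]:
            with np.errstate(divide="ignore"):
                logP = np.log(kernel(tree.edge_length[child]))
            scores = logP + L[child][None, :]
            back[(node, child)] = np.argmax(scores, axis=1)
            L[node] += np.max(scores, axis=1)
    with np.errstate(divide="ignore"):
        root_score = np.log(model.root_prior()) + L[tree.root]
    expanded = np.zeros(tree.n_nodes, dtype=np.int64)
    expanded[tree.root] = int(np.argmax(root_score))
    for node in tree.preorder:
        for child in tree.children[node]:
            expanded[child] = back[(node, child)][expanded[node]]
    return expanded % model.n_observed, expanded


# ------------------------------------------------------------------- fitting
def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    a = np.asarray(aicc_values, dtype=float)
    d = a - a.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


@dataclass
class FittedMk:
    model: MkModel
    lnL: float
    k: int
    aicc: float
    aicw: float = np.nan
    converged: bool = True


DEFAULT_GRID = [(tying, c) for tying in ("ER", "ARD") for c in (1, 2, 3, 4)]


def fit_mk_models(tree: Phylogeny, tip_states, model_grid=None, n_starts=10,
                  seed=None, bounds=(1e-9, 100.0), root="flat",
                  n_observed=4, tol=1e-8):
    """Maximum-likelihood fit of each model in the grid; sorted by AICc.

    Multi-start bounded optimization on log-scale rates.  Models whose AICc
    is undefined (too few tips) or that fail to converge are flagged and
    excluded from the Akaike weights.
    """
    from scipy.optimize import minimize

    if model_grid is None:
        model_grid = DEFAULT_GRID
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    tip_states = np.asarray(tip_states, dtype=np.int64)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    # heuristic rate scale: one expected change per edge on average
    base_rate = max(n_observed / max(tree.total_tree_length, 1e-12), bounds[0] * 10)
    fits = []
    for tying, n_classes in model_grid:
        proto = build_mk_generator(tying, n_classes,
                                   _init_params(tying, n_classes, base_rate, n_observed),
                                   n_observed=n_observed, root=root)
        k = proto.n_params

        def neg(x):
            m = build_mk_generator(tying, n_classes, np.exp(x),
                                   n_observed=n_observed, root=root)
            ll = mk_loglik(tree, tip_states, m)
            return np.inf if not np.isfinite(ll) else -ll

        best = None
        converged = False
        for s in range(n_starts):
            if s == 0:
                x0 = np.log(_init_params(tying, n_classes, base_rate, n_observed))
            else:
                x0 = rng.uniform(np.log(base_rate) - 3, np.log(base_rate) + 3, k)
            x0 = np.clip(x0, lo, hi)
            res = minimize(neg, x0, method="L-BFGS-B",
                           bounds=[(lo, hi)] * k, options={"ftol": tol})
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or res.success
        model = build_mk_generator(tying, n_classes, np.exp(best.x),
                                   n_observed=n_observed, root=root)
        lnL = -best.fun
        try:
            a = aicc(lnL, k, n)
        except ValueError:
            warnings.warn(
                f"AICc undefined for {tying}-{n_classes} with n={n}; flagged")
            converged, a = False, np.inf
        if not converged:
            warnings.warn(f"model {tying}-{n_classes} flagged (non-convergence "
                          "or undefined AICc); excluded from weights")
        fits.append(FittedMk(model=model, lnL=lnL, k=k, aicc=a,
                             converged=converged))
    ok = [f for f in fits if f.converged]
    if ok:
        w = akaike_weights([f.aicc for f in ok])
        for f, wi in zip(ok, w):
            f.aicw = float(wi)
    fits.sort(key=lambda f: f.aicc)
    return fits


def _init_params(tying, n_classes, base_rate, n_observed):
    n_within = n_classes if tying == "ER" else n_classes * n_observed * (n_observed - 1)
    scales = np.geomspace(0.2, 5.0, n_classes) if n_classes > 1 else np.ones(1)
    if tying == "ER":
        within = base_rate * scales
    else:
        within = np.repeat(base_rate * scales, n_observed * (n_observed - 1))
    params = list(within[:n_within])
    if n_classes > 1:
        params.append(base_rate / 10.0)
    return np.asarray(params)


# ------------------------------------------------------- stochastic mapping
def _cat(rng, w):
    """Draw an index proportional to nonnegative weights."""
    c = np.cumsum(w)
    if c[-1] <= 0:
        raise RuntimeError("no admissible state in categorical draw")
    return int(np.searchsorted(c, rng.random() * c[-1], side="right"))


#: hard cap on uniformization proposals per branch
MAX_UNIFORMIZATION_N = 10**6


class SimmapSampler:
    """Reusable sampler of stochastic character maps.

    Precomputes the pruning tables, transition matrices, Poisson terms and
    the dominating-chain power tensor so that repeated single-map draws
    (e.g. inside an outer MCMC) are cheap.  Dominating rate: 1.05 x max
    |Q_ii|.
    """

    def __init__(self, tree: Phylogeny, tip_states, model: MkModel):
        partial, _, kernel = _pruning(tree, tip_states, model)
        if partial is None:
            raise ValueError("data impossible under model")
        self.tree, self.model = tree, model
        self.partial, self.kernel = partial, kernel
        self.prior = model.root_prior()
        Q = model.Q
        K = model.n_states
        self.mu = 1.05 * float(np.max(-np.diag(Q)))
        self.R = np.eye(K) + Q / self.mu if self.mu > 0 else np.eye(K)
        # per-branch truncation of the dominating Poisson count
        self._branch_n = {}
        self._branch_pois = {}
        n_glob = 0
        for node in range(tree.n_nodes):
            if tree.parent[node] < 0:
                continue
            mu_t = self.mu * tree.edge_length[node]
            n_max = int(mu_t + 12.0 * np.sqrt(mu_t + 1.0) + 40)
            if n_max > MAX_UNIFORMIZATION_N:
                raise RuntimeError(
                    f"uniformization proposal cap exceeded on branch {node}")
            ns = np.arange(n_max + 1)
            with np.errstate(divide="ignore"):
                logp = (ns * np.log(mu_t) - mu_t - gammaln(ns + 1)
                        if mu_t > 0 else np.where(ns == 0, 0.0, -np.inf))
            self._branch_n[node] = n_max
            self._branch_pois[node] = logp
            n_glob = max(n_glob, n_max)
        # RP[n] = R^n; small state space makes this tensor cheap
        RP = np.empty((n_glob + 1, K, K))
        RP[0] = np.eye(K)
        for n in range(1, n_glob + 1):
            RP[n] = RP[n - 1] @ self.R
        self.RP = RP

    def _draw_path(self, node, a, b, rng):
        """Endpoint-conditioned changes [(time, new_state), ...] on a branch."""
        if self.mu <= 0.0:
            return []
        t = self.tree.edge_length[node]
        n_max = self._branch_n[node]
        logp = self._branch_pois[node]
        rab = self.RP[: n_max + 1, a, b]
        with np.errstate(divide="ignore", invalid="ignore"):
            logw = logp + np.log(rab)
        m = np.nanmax(logw)
        if not np.isfinite(m):
            raise RuntimeError(f"no endpoint-conditioned path on branch {node}")
        n_jumps = _cat(rng, np.exp(np.nan_to_num(logw - m, nan=-np.inf)))
        if n_jumps == 0:
            return []
        times = np.sort(rng.uniform(0.0, t, n_jumps))
        changes = []
        state = a
        for i in range(1, n_jumps + 1):
            new = _cat(rng, self.R[state] * self.RP[n_jumps - i, :, b])
            if new != state:
                changes.append((times[i - 1], new))
                state = new
        assert state == b
        return changes

    def draw(self, rng) -> BranchHistory:
        tree, partial = self.tree, self.partial
        states = np.zeros(tree.n_nodes, dtype=np.int64)
        states[tree.root] = _cat(rng, self.prior * partial[tree.root])
        segments = {}
        n_changes = 0
        for node in tree.preorder:
            for child in tree.children[node]:
                t = tree.edge_length[child]
                w = self.kernel(t)[states[node]] * partial[child]
                states[child] = _cat(rng, w)
                changes = self._draw_path(child, int(states[node]),
                                          int(states[child]), rng)
                segs = []
                prev_t, prev_s = 0.0, int(states[node])
                for ct, cs in changes:
                    segs.append((ct - prev_t, prev_s))
                    prev_t, prev_s = ct, cs
                segs.append((t - prev_t, prev_s))
                segments[child] = segs
                n_changes += len(changes)
        return BranchHistory(tree=tree, segments=segments,
                             node_states=states, n_changes=n_changes)

    def draw_subtree(self, history: BranchHistory, rng):
        """Redraw node states and paths below a random internal node.

        The state at the chosen node is kept fixed; the conditional draw
        below it leaves the simmap distribution invariant.  Returns a new
        BranchHistory.
        """
        tree = self.tree
        internals = np.arange(tree.n_tips, tree.n_nodes)
        v = int(internals[rng.integers(len(internals))])
        states = history.node_states.copy()
        segments = dict(history.segments)
        n_changes = history.n_changes
        stack = [v]
        while stack:
            node = stack.pop()
            for child in tree.children[node]:
                t = tree.edge_length[child]
                w = self.kernel(t)[states[node]] * self.partial[child]
                states[child] = _cat(rng, w)
                changes = self._draw_path(child, int(states[node]),
                                          int(states[child]), rng)
                segs = []
                prev_t, prev_s = 0.0, int(states[node])
                for ct, cs in changes:
                    segs.append((ct - prev_t, prev_s))
                    prev_t, prev_s = ct, cs
                segs.append((t - prev_t, prev_s))
                n_changes += len(changes) - (len(segments[child]) - 1)
                segments[child] = segs
                stack.append(child)
        return BranchHistory(tree=tree, segments=segments,
                             node_states=states, n_changes=n_changes)


def sample_stochastic_maps(tree: Phylogeny, tip_states, model: MkModel,
                           n_maps=1000, seed=None):
    """Exact posterior draws of full character histories given the model.

    Node states come from backward sampling off the pruning tables; branch
    interiors are endpoint-conditioned draws via uniformization.
    """
    rng = np.random.default_rng(seed)
    sampler = SimmapSampler(tree, tip_states, model)
    return [sampler.draw(rng) for _ in range(n_maps)]


# ----------------------------------------------------------------- occupancy
def occupancy_through_time(maps, n_observed=4, bin_width=1.0,
                           quantiles=(0.05, 0.95)) -> pd.DataFrame:
    """Proportion of lineage-time per observed state in 1-Myr bins.

    Bins run backward from the present; proportions are averaged over maps
    with the requested quantiles.  Hidden classes are collapsed onto their
    observed state.  Columns: bin_start, bin_end, state, mean, q05, q95.
    """
    if not maps:
        raise ValueError("need at least one map")
    tree = maps[0].tree
    ages = tree.node_ages()
    n_bins = int(np.ceil(ages.max() / bin_width - 1e-12))
    props = []
    for hist in maps:
        occ = hist.state_occupancy(
            n_observed, ages, bin_width, n_bins,
            observed_of=lambda s: s % n_observed)
        total = occ.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            props.append(np.where(total > 0, occ / total, np.nan))
    props = np.array(props)  # (n_maps, n_bins, n_states)
    rows = []
    for k in range(n_bins):
        if np.all(np.isnan(props[:, k, :])):
            continue
        for s in range(n_observed):
            vals = props[:, k, s]
            vals = vals[~np.isnan(vals)]
            rows.append({
                "bin_start": k * bin_width,
                "bin_end": (k + 1) * bin_width,
                "state": s,
                "mean": float(np.mean(vals)),
                "q05": float(np.quantile(vals, quantiles[0])),
                "q95": float(np.quantile(vals, quantiles[1])),
            })
    return pd.DataFrame(rows)
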