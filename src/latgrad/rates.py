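"""State-dependent rates of multivariate trait evolution.

Continuous traits evolve by independent-trait Brownian motion whose edge
variance for trait j is

    prop_j * sigma2_0 * sum_segments multiplier(edge) * zeta(state) * dur

with lognormal background edge multipliers (random local clock /
spike-and-slab shifts), state multipliers ``zeta`` constrained to mean 1,
and a Bernoulli(1/2) indicator ``delta`` that switches state dependence off
(zeta == 1) when 0.  MCMC samples the joint posterior, optionally redrawing
the discrete history by stochastic-mapping proposals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._bm import bm_loglik_parts, path_cumsum, tree_arrays
from .history import BranchHistory
from .phylo import Phylogeny

__all__ = [
    "RatePosterior",
    "TipRates",
    "RobustFit",
    "sdbm_loglik",
    "rlc_tip_rates",
    "musscrat_mcmc",
    "state_rate_ratios",
    "robust_phylo_regression",
    "effective_sample_size",
    "scale_prior_shifts",
]

#: branch count of the empirical tree the shift-prior grid was stated for
_PAPER_N_BRANCHES = 2 * 3183 - 2


def scale_prior_shifts(prior_n_shifts: float, n_edges: int) -> float:
    """Scale an expected shift count proportionally to tree size."""
    return prior_n_shifts * n_edges / _PAPER_N_BRANCHES


def _traits_matrix(tree: Phylogeny, traits) -> np.ndarray:
    if isinstance(traits, pd.DataFrame):
        return traits.loc[tree.tip_labels].to_numpy(dtype=float)
    X = np.asarray(traits, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def _assemble_loglik(q, logdet, scales, n):
    p = scales.size
    return float(-0.5 * np.sum(q / scales + n * np.log(scales))
                 - 0.5 * p * (logdet + n * np.log(2.0 * np.pi)))


def sdbm_loglik(tree: Phylogeny, traits, history: BranchHistory = None,
                sigma2_0=1.0, branch_multipliers=None, zeta=None,
                trait_props=None) -> float:
    """Log-likelihood of tip traits under state-dependent relaxed BM.

    Root trait values are profiled out at their GLS means.  With no history
    and unit multipliers this is plain multivariate BM.
    """
    X = _traits_matrix(tree, traits)
    p = X.shape[1]
    if sigma2_0 <= 0:
        raise ValueError("sigma2_0 must be > 0")
    if history is not None:
        n_states = int(history.node_states.max()) + 1
        z = np.ones(n_states) if zeta is None else np.asarray(zeta, float)
        if np.any(z <= 0):
            raise ValueError("state multipliers must be > 0")
        eff = history.effective_edge_lengths(z)
    else:
        eff = tree.edge_length.copy()
    mult = np.ones(tree.n_nodes) if branch_multipliers is None else \
        np.asarray(branch_multipliers, dtype=float)
    if np.any(mult <= 0):
        raise ValueError("branch multipliers must be > 0")
    edge_var = mult * eff
    edge_var[tree.root] = 0.0
    props = np.ones(p) if trait_props is None else np.asarray(trait_props, float)
    scales = props * sigma2_0
    arrays = tree_arrays(tree)
    q, logdet, _ = bm_loglik_parts(arrays, tree.n_tips, edge_var, X)
    return _assemble_loglik(q, logdet, scales, tree.n_tips)


# =====================================================================  MCMC
@dataclass
class TipRates:
    """Posterior summary of species-specific (terminal-branch) rates."""

    table: pd.DataFrame  # species, mean, q025, q975
    samples: np.ndarray = None  # (n_stored, n_tips)


@dataclass
class RatePosterior:
    """Thinned MCMC samples from the state-dependent rate model."""

    traces: pd.DataFrame          # scalar parameters per stored sample
    zeta: np.ndarray = None       # (n_stored, n_states)
    tip_rates: TipRates = None
    branch_rate_mean: np.ndarray = None
    state_names: list = None
    ess_sigma2: float = np.nan
    ess_warning: bool = False

    @property
    def p_state_dependent(self) -> float:
        return float(self.traces["delta_state"].mean())


def effective_sample_size(x) -> float:
    """ESS from the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    if acov[0] <= 0:
        return float(n)
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


class _Sampler:
    """Shared Metropolis-within-Gibbs sampler for the rate models."""

    def __init__(self, tree, X, prior_n_shifts, seed, history=None,
                 n_states=4, state_dependent=False, shift_sd=np.log(2.0),
                 sigma2_log_prior=(0.0, 1.5), likelihood_on=True,
                 mk_model=None, tip_states=None, history_interval=25,
                 edges_per_sweep=4):
        self.tree = tree
        self.X = X
        self.n, self.p = X.shape
        self.rng = np.random.default_rng(seed)
        self.arrays = tree_arrays(tree)
        self.preorder = tree.preorder.astype(np.int64)
        self.parent = tree.parent.astype(np.int64)
        self.has_edge = tree.parent >= 0
        self.n_edges = int(self.has_edge.sum())
        self.edge_nodes = np.flatnonzero(self.has_edge)
        self.p_shift = min(max(prior_n_shifts / self.n_edges, 1e-6), 0.9)
        self.shift_sd = shift_sd
        self.s2_mu, self.s2_sd = sigma2_log_prior
        self.likelihood_on = likelihood_on
        self.n_states = n_states
        self.state_dependent = state_dependent
        self.mk_model = mk_model
        self.tip_states = tip_states
        self.history_interval = history_interval
        self.edges_per_sweep = edges_per_sweep
        self.simmap = None
        if mk_model is not None and tip_states is not None:
            from .discrete import SimmapSampler

            self.simmap = SimmapSampler(tree, tip_states, mk_model)
        # adaptive proposal scales (tuned during burnin only)
        self.steps = {"sigma2": 0.3, "zeta": 0.1, "props": 0.05, "logm": 0.4}
        self._acc = {k: [0, 0] for k in self.steps}
        self._adapting = True

        # --- state
        self.log_sigma2 = float(self.rng.normal(self.s2_mu, 0.1))
        self.delta_e = np.zeros(tree.n_nodes, dtype=bool)
        self.log_m = self.rng.normal(0.0, shift_sd, tree.n_nodes)
        self.zeta_w = np.full(n_states, 1.0 / n_states)
        self.delta_state = 1 if state_dependent else 0
        self.props_w = np.full(self.p, 1.0 / self.p)
        self.history = history
        if self.history is None and self.simmap is not None:
            self.history = self.simmap.draw(self.rng)
        self._refresh_state_durations()
        self._q = None
        self._logdet = None
        self._recompute_edge_var()

    # ----- bookkeeping
    def _refresh_state_durations(self):
        """(n_nodes, n_states) per-edge time spent in each state."""
        S = np.zeros((self.tree.n_nodes, self.n_states))
        if self.history is None:
            S[self.edge_nodes, 0] = self.tree.edge_length[self.edge_nodes]
        else:
            for node, segs in self.history.segments.items():
                for dur, st in segs:
                    S[node, st % self.n_states] += dur
        self._state_dur = S

    @property
    def zeta(self):
        return self.n_states * self.zeta_w

    @property
    def zeta_eff(self):
        return self.zeta if self.delta_state else np.ones(self.n_states)

    @property
    def trait_props(self):
        return self.p * self.props_w

    def _branch_log_rates(self):
        x = np.where(self.delta_e, self.log_m, 0.0)
        x[self.tree.root] = 0.0
        return path_cumsum(self.preorder, self.parent, x)

    def _recompute_edge_var(self):
        log_r = self._branch_log_rates()
        eff = self._state_dur @ self.zeta_eff
        ev = np.exp(log_r) * eff
        ev[self.tree.root] = 0.0
        self._edge_var = ev
        if self.likelihood_on:
            self._q, self._logdet, _ = bm_loglik_parts(
                self.arrays, self.n, ev, self.X)

    def _loglik(self, q=None, logdet=None, log_sigma2=None, props_w=None):
        if not self.likelihood_on:
            return 0.0
        q = self._q if q is None else q
        logdet = self._logdet if logdet is None else logdet
        ls = self.log_sigma2 if log_sigma2 is None else log_sigma2
        pw = self.props_w if props_w is None else props_w
        scales = (self.p * pw) * np.exp(ls)
        return _assemble_loglik(q, logdet, scales, self.n)

    def _try_edge_var(self):
        """Pruning parts for a tentative state (returns q, logdet, lnL)."""
        log_r = self._branch_log_rates()
        eff = self._state_dur @ self.zeta_eff
        ev = np.exp(log_r) * eff
        ev[self.tree.root] = 0.0
        if not self.likelihood_on:
            return None, None, 0.0, ev
        q, logdet, _ = bm_loglik_parts(self.arrays, self.n, ev, self.X)
        return q, logdet, self._loglik(q=q, logdet=logdet), ev

    # ----- adaptation
    def _record(self, key, accepted):
        if not self._adapting:
            return
        acc = self._acc[key]
        acc[0] += accepted
        acc[1] += 1
        if acc[1] >= 50:
            rate = acc[0] / acc[1]
            self.steps[key] *= float(np.exp(0.5 * (rate - 0.35)))
            self.steps[key] = float(np.clip(self.steps[key], 1e-4, 5.0))
            acc[0] = acc[1] = 0

    # ----- moves
    def _move_sigma2(self):
        prop = self.log_sigma2 + self.rng.normal(0.0, self.steps["sigma2"])
        d_prior = (-0.5 * ((prop - self.s2_mu) / self.s2_sd) ** 2
                   + 0.5 * ((self.log_sigma2 - self.s2_mu) / self.s2_sd) ** 2)
        d_lik = self._loglik(log_sigma2=prop) - self._loglik()
        ok = np.log(self.rng.random()) < d_prior + d_lik
        if ok:
            self.log_sigma2 = prop
        self._record("sigma2", ok)

    def _pick_edge(self):
        return int(self.edge_nodes[self.rng.integers(self.n_edges)])

    def _move_edges(self):
        cur_lnl = self._loglik()
        logit = np.log(self.p_shift / (1.0 - self.p_shift))
        for _ in range(self.edges_per_sweep):
            e = self._pick_edge()
            # flip indicator
            self.delta_e[e] = ~self.delta_e[e]
            q, logdet, lnl, ev = self._try_edge_var()
            d_prior = logit if self.delta_e[e] else -logit
            if np.log(self.rng.random()) < d_prior + lnl - cur_lnl:
                self._q, self._logdet, self._edge_var = q, logdet, ev
                cur_lnl = lnl
            else:
                self.delta_e[e] = ~self.delta_e[e]
            # magnitude update
            e2 = self._pick_edge()
            if not self.delta_e[e2]:
                self.log_m[e2] = self.rng.normal(0.0, self.shift_sd)
                continue
            old = self.log_m[e2]
            self.log_m[e2] = old + self.rng.normal(0.0, self.steps["logm"])
            q, logdet, lnl, ev = self._try_edge_var()
            d_prior = -0.5 * ((self.log_m[e2] / self.shift_sd) ** 2
                              - (old / self.shift_sd) ** 2)
            ok = np.log(self.rng.random()) < d_prior + lnl - cur_lnl
            if ok:
                self._q, self._logdet, self._edge_var = q, logdet, ev
                cur_lnl = lnl
            else:
                self.log_m[e2] = old
            self._record("logm", ok)

    #: concentration of the Dirichlet bridge proposal used when switching
    #: state dependence on (proposes zeta near 1 so the jump is likelihood-
    #: neutral and the slab can then random-walk to its posterior)
    _BRIDGE_CONC = 50.0

    def _log_dirichlet(self, w, alpha):
        from scipy.special import gammaln as gl

        a = np.broadcast_to(alpha, w.shape)
        return float(gl(a.sum()) - gl(a).sum() + np.sum((a - 1.0) * np.log(w)))

    def _move_zeta(self):
        if not self.state_dependent:
            return
        K = self.n_states
        if self.delta_state == 0:
            # zeta is not a model parameter while dependence is off; keep
            # the stored slab an exact prior draw
            self.zeta_w = self.rng.dirichlet(np.ones(K))
        if self.delta_state == 1:
            # pairwise transfer keeping mean(zeta) = 1
            i = int(self.rng.integers(K))
            j = int((i + 1 + self.rng.integers(K - 1)) % K)
            d = self.rng.uniform(-self.steps["zeta"], self.steps["zeta"])
            w = self.zeta_w.copy()
            w[i] += d
            w[j] -= d
            if w[i] > 0 and w[j] > 0:
                old_lnl = self._loglik()
                old_w = self.zeta_w
                self.zeta_w = w
                q, logdet, lnl, ev = self._try_edge_var()
                ok = np.log(self.rng.random()) < lnl - old_lnl
                if ok:
                    self._q, self._logdet, self._edge_var = q, logdet, ev
                else:
                    self.zeta_w = old_w
                self._record("zeta", ok)
        # reversible-jump flip of the state-dependence indicator
        conc = np.full(K, self._BRIDGE_CONC)
        prior_a = np.ones(K)
        old_lnl = self._loglik()
        if self.delta_state == 0:
            w_new = self.rng.dirichlet(conc)
            old_w = self.zeta_w
            self.zeta_w = w_new
            self.delta_state = 1
            q, logdet, lnl, ev = self._try_edge_var()
            log_r = (lnl - old_lnl
                     + self._log_dirichlet(w_new, prior_a)
                     - self._log_dirichlet(w_new, conc))
            if np.log(self.rng.random()) < log_r:
                self._q, self._logdet, self._edge_var = q, logdet, ev
            else:
                self.delta_state = 0
                self.zeta_w = old_w
        else:
            w_cur = self.zeta_w
            self.delta_state = 0
            q, logdet, lnl, ev = self._try_edge_var()
            log_r = (lnl - old_lnl
                     + self._log_dirichlet(w_cur, conc)
                     - self._log_dirichlet(w_cur, prior_a))
            if np.log(self.rng.random()) < log_r:
                self._q, self._logdet, self._edge_var = q, logdet, ev
            else:
                self.delta_state = 1

    def _move_props(self):
        if self.p < 2:
            return
        i = int(self.rng.integers(self.p))
        j = int((i + 1 + self.rng.integers(self.p - 1)) % self.p)
        d = self.rng.uniform(-self.steps["props"], self.steps["props"])
        w = self.props_w.copy()
        w[i] += d
        w[j] -= d
        if w[i] <= 0 or w[j] <= 0:
            return
        d_lik = self._loglik(props_w=w) - self._loglik()
        ok = np.log(self.rng.random()) < d_lik
        if ok:
            self.props_w = w
        self._record("props", ok)

    def _move_history(self, full=False):
        if self.simmap is None or self.history is None:
            return
        prop = (self.simmap.draw(self.rng) if full
                else self.simmap.draw_subtree(self.history, self.rng))
        old_lnl = self._loglik()
        old_hist, old_dur = self.history, self._state_dur
        self.history = prop
        self._refresh_state_durations()
        q, logdet, lnl, ev = self._try_edge_var()
        if np.log(self.rng.random()) < lnl - old_lnl:
            self._q, self._logdet, self._edge_var = q, logdet, ev
        else:
            self.history, self._state_dur = old_hist, old_dur

    # ----- main loop
    def run(self, iters, burnin=0.1, max_stored=10000):
        n_burn = int(burnin * iters)
        thin = max(1, (iters - n_burn) // max_stored)
        store = {k: [] for k in ("sigma2_0", "n_shifts", "delta_state")}
        zeta_samples = []
        props_samples = []
        tip_samples = []
        branch_rate_sum = np.zeros(self.tree.n_nodes)
        n_stored = 0
        for it in range(iters):
            if it == n_burn:
                self._adapting = False
            self._move_sigma2()
            self._move_edges()
            self._move_zeta()
            self._move_props()
            if (self.simmap is not None
                    and self.history_interval
                    and it % self.history_interval == 0):
                full = (it % (10 * self.history_interval)) == 0
                self._move_history(full=full)
            if it >= n_burn and (it - n_burn) % thin == 0:
                s2 = np.exp(self.log_sigma2)
                store["sigma2_0"].append(s2)
                store["n_shifts"].append(int(self.delta_e.sum()))
                store["delta_state"].append(self.delta_state)
                zeta_samples.append(self.zeta.copy())
                props_samples.append(self.trait_props.copy())
                r = np.exp(self._branch_log_rates())
                branch_rate_sum += r * s2
                tip_samples.append(r[: self.tree.n_tips] * s2)
                n_stored += 1
        traces = pd.DataFrame(store)
        traces[[f"prop_{j + 1}" for j in range(self.p)]] = np.array(props_samples)
        return traces, np.array(zeta_samples), np.array(tip_samples), \
            branch_rate_sum / max(n_stored, 1)


def _tip_rate_table(tree, tip_samples):
    mean = tip_samples.mean(axis=0)
    lo = np.quantile(tip_samples, 0.025, axis=0)
    hi = np.quantile(tip_samples, 0.975, axis=0)
    return TipRates(
        table=pd.DataFrame({"species": tree.tip_labels, "mean": mean,
                            "q025": lo, "q975": hi}),
        samples=tip_samples,
    )


def rlc_tip_rates(tree: Phylogeny, traits, prior_n_shifts, iters=300_000,
                  burnin=0.1, seed=None, likelihood_on=True,
                  **sampler_kwargs):
    """Random-local-clock MCMC; tip rate = terminal-edge rate x sigma2_0.

    ``prior_n_shifts`` is the expected number of rate shifts (spike-and-slab
    Bernoulli per edge, i.i.d. lognormal shift magnitudes).
    """
    X = _traits_matrix(tree, traits)
    smp = _Sampler(tree, X, prior_n_shifts, seed, likelihood_on=likelihood_on,
                   state_dependent=False, **sampler_kwargs)
    traces, _, tip_samples, branch_mean = smp.run(iters, burnin=burnin)
    post = RatePosterior(traces=traces, tip_rates=_tip_rate_table(tree, tip_samples),
                         branch_rate_mean=branch_mean)
    post.ess_sigma2 = effective_sample_size(traces["sigma2_0"].to_numpy())
    if post.ess_sigma2 < 200:
        post.ess_warning = True
        warnings.warn(f"sigma2_0 ESS {post.ess_sigma2:.0f} < 200")
    return post


def musscrat_mcmc(tree: Phylogeny, traits, tip_states, mk_model=None,
                  prior_n_shifts=500, iters=300_000, burnin=0.1, seed=None,
                  history_interval=25, state_names=None, scale_prior=True,
                  likelihood_on=True, **sampler_kwargs):
    """Joint MCMC over background rates, state multipliers and histories.

    ``mk_model`` (a fitted :class:`~latgrad.discrete.MkModel`) drives the
    stochastic-map redraws; if None an ER 1-class model is fit by ML first.
    The shift prior is scaled to tree size when ``scale_prior`` is True.
    """
    from .discrete import fit_mk_models

    tip_states = np.asarray(tip_states, dtype=np.int64)
    n_states = int(tip_states.max()) + 1
    if mk_model is None:
        fits = fit_mk_models(tree, tip_states, model_grid=[("ER", 1)],
                             n_starts=4, seed=seed, n_observed=n_states)
        mk_model = fits[0].model
    X = _traits_matrix(tree, traits)
    if scale_prior:
        prior_n_shifts = scale_prior_shifts(prior_n_shifts, 2 * tree.n_tips - 2)
    smp = _Sampler(tree, X, prior_n_shifts, seed, history=None,
                   n_states=mk_model.n_observed, state_dependent=True,
                   mk_model=mk_model, tip_states=tip_states,
                   history_interval=history_interval,
                   likelihood_on=likelihood_on, **sampler_kwargs)
    traces, zeta, tip_samples, branch_mean = smp.run(iters, burnin=burnin)
    post = RatePosterior(
        traces=traces, zeta=zeta,
        tip_rates=_tip_rate_table(tree, tip_samples),
        branch_rate_mean=branch_mean,
        state_names=state_names or [str(i) for i in range(mk_model.n_observed)],
    )
    post.ess_sigma2 = effective_sample_size(traces["sigma2_0"].to_numpy())
    if post.ess_sigma2 < 200:
        post.ess_warning = True
        warnings.warn(f"sigma2_0 ESS {post.ess_sigma2:.0f} < 200")
    return post


def state_rate_ratios(posterior: RatePosterior) -> pd.DataFrame:
    """Posterior fold-differences zeta_a / zeta_b for all ordered pairs.

    Uses samples with the state-dependence indicator on when enough exist
    (the multipliers are pinned at 1 when it is off).
    """
    if posterior.zeta is None or len(posterior.zeta) == 0:
        raise ValueError("posterior holds no state-multiplier samples")
    Z = posterior.zeta
    if "delta_state" in posterior.traces:
        on = posterior.traces["delta_state"].to_numpy().astype(bool)
        if on.sum() >= 100:
            Z = Z[on]
    names = posterior.state_names or [str(i) for i in range(Z.shape[1])]
    rows = []
    for a in range(Z.shape[1]):
        for b in range(Z.shape[1]):
            if a == b:
                continue
            r = Z[:, a] / Z[:, b]
            rows.append({"state_a": names[a], "state_b": names[b],
                         "mean": float(r.mean()),
                         "q025": float(np.quantile(r, 0.025)),
                         "q975": float(np.quantile(r, 0.975))})
    return pd.DataFrame(rows)


# ------------------------------------------------------- robust regression
@dataclass
class RobustFit:
    slope: float
    intercept: float
    r2: float
    p_value: float
    slope_se: float


def robust_phylo_regression(tree: Phylogeny, y, x,
                            huber_k: float = 1.345) -> RobustFit:
    """Phylogenetic regression with Huber M-estimation.

    Responses and design are whitened by the inverse Cholesky factor of the
    BM tree covariance, then fit by iteratively reweighted least squares
    with a Huber loss.  The robust R^2 compares Huber losses of the full
    fit and an intercept-only fit on the whitened scale.
    """
    import statsmodels.api as sm
    from scipy.linalg import cholesky, solve_triangular

    y = np.asarray(pd.Series(y).loc[tree.tip_labels]
                   if isinstance(y, pd.Series) else y, dtype=float)
    x = np.asarray(pd.Series(x).loc[tree.tip_labels]
                   if isinstance(x, pd.Series) else x, dtype=float)
    n = len(y)
    C = tree.vcv()
    L = cholesky(C, lower=True)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, np.column_stack([np.ones(n), x]), lower=True)
    if np.linalg.matrix_rank(Xw) < 2:
        raise ValueError("singular design (constant predictor)")
    norm = sm.robust.norms.HuberT(t=huber_k)
    fit = sm.RLM(yw, Xw, M=norm).fit()
    base = sm.RLM(yw, Xw[:, :1], M=norm).fit()
    scale = max(fit.scale, 1e-300)
    loss_full = norm.rho(fit.resid / scale).sum()
    loss_base = norm.rho(base.resid / scale).sum()
    r2 = 1.0 - loss_full / loss_base if loss_base > 0 else 1.0
    return RobustFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(np.clip(r2, 0.0, 1.0)),
        p_value=float(fit.pvalues[1]),
        slope_se=float(fit.bse[1]),
    )
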