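import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from latgrad import discrete as dc
from latgrad import synthetic as syn
from latgrad.history import BranchHistory
from latgrad.phylo import Phylogeny


# ---------------------------------------------------------------- oracles
def enum_loglik(tree, tips, Q, prior):
    """Brute-force sum over all internal-node state assignments."""
    n = tree.n_tips
    internals = [i for i in range(tree.n_nodes) if i >= n]
    K = Q.shape[0]
    Ps = {node: expm(Q * tree.edge_length[node])
          for node in range(tree.n_nodes) if tree.parent[node] >= 0}
    tot = 0.0
    for assign in itertools.product(range(K), repeat=len(internals)):
        st = dict(zip(internals, assign))
        for i in range(n):
            st[i] = tips[i]
        p = prior[st[tree.root]]
        for node, P in Ps.items():
            p *= P[st[tree.parent[node]], st[node]]
        tot += p
    return np.log(tot) if tot > 0 else -np.inf


def enum_joint_argmax(tree, tips, Q, prior):
    """Brute-force jointly most probable internal assignment."""
    n = tree.n_tips
    internals = [i for i in range(tree.n_nodes) if i >= n]
    K = Q.shape[0]
    Ps = {node: expm(Q * tree.edge_length[node])
          for node in range(tree.n_nodes) if tree.parent[node] >= 0}
    best, best_p = None, -1.0
    for assign in itertools.product(range(K), repeat=len(internals)):
        st = dict(zip(internals, assign))
        for i in range(n):
            st[i] = tips[i]
        p = prior[st[tree.root]]
        for node, P in Ps.items():
            p *= P[st[tree.parent[node]], st[node]]
        if p > best_p:
            best_p, best = p, dict(st)
    return best


# ------------------------------------------------------------- generators
class TestGenerator:
    def test_er_one_class(self):
        m = dc.build_mk_generator("ER", 1, {"within": 0.3})
        Q = m.Q
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.3)
        assert np.allclose(np.diag(Q), -0.9)
        assert m.n_params == 1

    def test_er_two_classes(self):
        m = dc.build_mk_generator("ER", 2, {"within": [0.1, 1.0], "switch": 0.05})
        Q = m.Q
        assert Q.shape == (8, 8)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert Q[0, 1] == pytest.approx(0.1)
        assert Q[4, 5] == pytest.approx(1.0)
        assert Q[0, 4] == pytest.approx(0.05)   # class switch keeps state
        assert Q[0, 5] == 0.0                   # no joint switch+transition
        assert m.n_params == 3

    def test_ard_rate_order(self):
        rates = np.arange(1.0, 13.0)
        m = dc.build_mk_generator("ARD", 1, {"within": rates})
        Q = m.Q
        for r, (i, j) in zip(rates, dc.ARD_PAIRS):
            assert Q[i, j] == pytest.approx(r)
        assert m.n_params == 12

    def test_negative_rate_errors(self):
        with pytest.raises(ValueError):
            dc.build_mk_generator("ER", 1, {"within": -0.1})


# ------------------------------------------------------------- likelihood
class TestLoglik:
    def test_two_tips_same_state_q_zero(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        m = dc.MkModel("ER", 1, [0.0], n_observed=4)
        ll = dc.mk_loglik(tree, [2, 2], m)
        assert ll == pytest.approx(np.log(0.25))

    def test_two_tips_discordant_q_zero(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        m = dc.MkModel("ER", 1, [0.0], n_observed=4)
        assert dc.mk_loglik(tree, [0, 1], m) == -np.inf

    def test_four_tip_enumeration(self, balanced_four_tree):
        m = dc.build_mk_generator("ER", 1, {"within": 0.5}, n_observed=2)
        tips = np.array([0, 1, 1, 0])
        ll = dc.mk_loglik(balanced_four_tree, tips, m)
        oracle = enum_loglik(balanced_four_tree, tips, m.Q, m.root_prior())
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_enumeration_property_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(3, 6))
            tree = syn.simulate_bd_tree(n, 1.0, 0.0, seed=rng)
            K = int(rng.integers(2, 5))
            tying = "ER" if rng.random() < 0.5 else "ARD"
            if tying == "ER":
                m = dc.MkModel(tying, 1, rng.uniform(0.05, 1.0, 1), n_observed=K)
                # MkModel ER builds K-state generator via n_observed
            else:
                npairs = K * (K - 1)
                m = dc.MkModel("ARD", 1, rng.uniform(0.05, 1.0, npairs),
                               n_observed=K)
            tips = rng.integers(0, K, n)
            ll = dc.mk_loglik(tree, tips, m)
            oracle = enum_loglik(tree, tips, m.Q, m.root_prior())
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_hidden_class_collapse(self, balanced_four_tree):
        m1 = dc.build_mk_generator("ER", 1, {"within": 0.3})
        m2 = dc.build_mk_generator("ER", 2, {"within": [0.3, 0.3], "switch": 0.0})
        m3 = dc.build_mk_generator("ER", 2, {"within": [0.3, 0.3], "switch": 0.7})
        tips = [0, 1, 2, 3]
        l1 = dc.mk_loglik(balanced_four_tree, tips, m1)
        assert dc.mk_loglik(balanced_four_tree, tips, m2) == pytest.approx(l1, abs=1e-10)
        # identical class rates: switch rate is irrelevant even when nonzero
        assert dc.mk_loglik(balanced_four_tree, tips, m3) == pytest.approx(l1, abs=1e-10)

    def test_tip_order_invariance(self):
        m = dc.build_mk_generator("ER", 1, {"within": 0.4}, n_observed=2)
        t1 = Phylogeny.from_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        t2 = Phylogeny.from_newick("((D:1,C:1):0.5,(B:1,A:1):0.5);")
        states = {"A": 0, "B": 1, "C": 1, "D": 0}
        l1 = dc.mk_loglik(t1, [states[l] for l in t1.tip_labels], m)
        l2 = dc.mk_loglik(t2, [states[l] for l in t2.tip_labels], m)
        assert l1 == pytest.approx(l2, abs=1e-12)

    def test_reroot_invariance_reversible(self):
        # same unrooted tree rooted on a different edge; ER is reversible
        # with uniform stationary frequencies = flat root prior
        m = dc.build_mk_generator("ER", 1, {"within": 0.4}, n_observed=3)
        t1 = Phylogeny.from_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        t2 = Phylogeny.from_newick("(A:0.3,(B:1,(C:1,D:1):1.0):0.7);")
        states = {"A": 0, "B": 1, "C": 2, "D": 0}
        l1 = dc.mk_loglik(t1, [states[l] for l in t1.tip_labels], m)
        l2 = dc.mk_loglik(t2, [states[l] for l in t2.tip_labels], m)
        assert l1 == pytest.approx(l2, abs=1e-10)


# ------------------------------------------------------------- model choice
class TestAicc:
    def test_formula(self):
        assert dc.aicc(-100, 3, 50) == pytest.approx(206 + 24 / 46)

    def test_large_n_limit(self):
        assert dc.aicc(-100, 3, 10**9) == pytest.approx(206.0, abs=1e-6)

    def test_undefined(self):
        with pytest.raises(ValueError):
            dc.aicc(-100, 3, 4)

    def test_weights(self):
        w = dc.akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)


class TestFit:
    @pytest.fixture(scope="class")
    def er_data(self):
        tree = syn.simulate_bd_tree(150, 1.0, 0.0, seed=21)
        rate = 2.0 / tree.root_age
        q = np.full((4, 4), rate)
        np.fill_diagonal(q, -3 * rate)
        h = syn.simulate_mk_history(tree, q, seed=22)
        return tree, h.tip_states

    def test_nesting_and_weights(self, er_data):
        tree, tips = er_data
        fits = dc.fit_mk_models(tree, tips, model_grid=[("ER", 1), ("ARD", 1)],
                                n_starts=3, seed=0)
        by = {f.model.tying: f for f in fits}
        assert by["ARD"].lnL >= by["ER"].lnL - 1e-4
        ws = [f.aicw for f in fits if f.converged]
        assert np.isclose(sum(ws), 1.0, atol=1e-10)

    def test_er_recovered(self, er_data):
        # data simulated under ER-1: it should sit near the top of the grid
        tree, tips = er_data
        fits = dc.fit_mk_models(tree, tips,
                                model_grid=[("ER", 1), ("ER", 2), ("ARD", 1)],
                                n_starts=3, seed=1)
        best = fits[0].aicc
        er1 = next(f for f in fits if f.model.tying == "ER"
                   and f.model.n_classes == 1)
        assert er1.aicc - best < 4.0


# --------------------------------------------------------- ancestral states
class TestJointAncestral:
    def test_near_zero_rates(self, balanced_four_tree):
        m = dc.MkModel("ER", 1, [1e-8], n_observed=4)
        obs, _ = dc.joint_ancestral_states(balanced_four_tree, [2, 2, 2, 2], m)
        assert (obs == 2).all()

    def test_matches_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(3, 6))
            tree = syn.simulate_bd_tree(n, 1.0, 0.0, seed=rng)
            m = dc.MkModel("ARD", 1, rng.uniform(0.1, 0.8, 2), n_observed=2)
            tips = rng.integers(0, 2, n)
            obs, _ = dc.joint_ancestral_states(tree, tips, m)
            oracle = enum_joint_argmax(tree, tips, m.Q, m.root_prior())
            for node in range(tree.n_tips, tree.n_nodes):
                assert obs[node] == oracle[node]

    def test_symmetric_tie_breaks_low(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        m = dc.build_mk_generator("ER", 1, {"within": 0.3})
        ia, ib = tree.tip_labels.index("A"), tree.tip_labels.index("B")
        tips = np.zeros(2, dtype=int)
        tips[ia], tips[ib] = 1, 2
        obs, _ = dc.joint_ancestral_states(tree, tips, m)
        assert obs[tree.root] == 1  # lowest of the two tied states


# --------------------------------------------------------- stochastic maps
class TestSimmap:
    def test_near_zero_rate_no_changes(self, balanced_four_tree):
        m = dc.MkModel("ER", 1, [1e-9], n_observed=3)
        maps = dc.sample_stochastic_maps(balanced_four_tree, [1, 1, 1, 1], m,
                                         n_maps=50, seed=0)
        assert all(mp.n_changes == 0 for mp in maps)

    def test_maps_consistent(self, balanced_four_tree):
        m = dc.build_mk_generator("ER", 1, {"within": 0.4}, n_observed=2)
        maps = dc.sample_stochastic_maps(balanced_four_tree, [0, 1, 1, 0], m,
                                         n_maps=100, seed=1)
        for mp in maps:
            mp.validate()
            assert np.array_equal(mp.tip_states % 2, [0, 1, 1, 0])

    def test_node_frequencies_match_marginals(self, balanced_four_tree):
        m = dc.build_mk_generator("ER", 1, {"within": 0.5}, n_observed=2)
        tips = [0, 1, 1, 0]
        marg = dc.marginal_ancestral_probs(balanced_four_tree, tips, m)
        n_maps = 5000
        maps = dc.sample_stochastic_maps(balanced_four_tree, tips, m,
                                         n_maps=n_maps, seed=2)
        freq = np.zeros_like(marg)
        for mp in maps:
            for node, s in enumerate(mp.node_states):
                freq[node, s] += 1
        freq /= n_maps
        se = np.sqrt(np.clip(marg * (1 - marg), 1e-12, None) / n_maps)
        assert np.all(np.abs(freq - marg) <= 3 * se + 1e-9)

    def test_conditioned_mean_changes(self):
        # single branch with fixed unequal endpoints: mean change count
        # matches the Van Loan integral E[N | a,b,t]
        q = np.array([[-0.6, 0.6], [0.4, -0.4]])
        a, b, t = 0, 1, 1.3
        C = q - np.diag(np.diag(q))
        M = np.block([[q, C], [np.zeros_like(q), q]])
        oracle = expm(M * t)[:2, 2:][a, b] / expm(q * t)[a, b]
        tree = Phylogeny.from_newick(f"(A:{t},B:0.0001);")
        m = dc.MkModel("ARD", 1, [0.6, 0.4], n_observed=2)
        sampler = dc.SimmapSampler(tree, [0, 0], m)
        rng = np.random.default_rng(3)
        ia = tree.tip_labels.index("A")
        counts = [len(sampler._draw_path(ia, a, b, rng)) for _ in range(10000)]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - oracle) < 3 * se

    def test_simmap_newick_serialization(self, balanced_four_tree):
        m = dc.build_mk_generator("ER", 1, {"within": 0.4}, n_observed=2)
        mp = dc.sample_stochastic_maps(balanced_four_tree, [0, 1, 1, 0], m,
                                       n_maps=1, seed=4)[0]
        s = mp.to_simmap_newick(state_names=["x", "y"])
        assert s.endswith(";") and "{" in s and "," in s


# ----------------------------------------------------------------- occupancy
class TestOccupancy:
    def _const_history(self, tree, state, n_states=2):
        segs = {n: [(tree.edge_length[n], state)]
                for n in range(tree.n_nodes) if tree.parent[n] >= 0}
        return BranchHistory(tree=tree,
                             segments=segs,
                             node_states=np.full(tree.n_nodes, state),
                             n_changes=0)

    def test_single_state(self, balanced_four_tree):
        h = self._const_history(balanced_four_tree, 1)
        prof = dc.occupancy_through_time([h], n_observed=2, bin_width=0.5)
        ones = prof[prof.state == 1]
        assert np.allclose(ones["mean"], 1.0)

    def test_hand_built_change_at_midpoint(self):
        # two branches of 2 Myr; one switches state at 1 Myr: the single
        # 2-Myr bin holds 3 Myr state 0 and 1 Myr state 1 -> (0.75, 0.25)
        tree = Phylogeny.from_newick("(A:2,B:2);")
        ia, ib = tree.tip_labels.index("A"), tree.tip_labels.index("B")
        ns = np.zeros(3, dtype=int)
        ns[ia] = 1
        h = BranchHistory(tree=tree,
                          segments={ia: [(1.0, 0), (1.0, 1)],
                                    ib: [(2.0, 0)]},
                          node_states=ns, n_changes=1)
        prof = dc.occupancy_through_time([h], n_observed=2, bin_width=2.0)
        got = prof.set_index("state")["mean"]
        assert got[0] == pytest.approx(0.75)
        assert got[1] == pytest.approx(0.25)

    def test_bins_sum_to_one(self, bd_tree_50):
        q = np.full((4, 4), 0.1)
        np.fill_diagonal(q, -0.3)
        m = dc.MkModel("ER", 1, [0.1], n_observed=4)
        h = syn.simulate_mk_history(bd_tree_50, q, seed=5)
        maps = dc.sample_stochastic_maps(bd_tree_50, h.tip_states, m,
                                         n_maps=5, seed=6)
        prof = dc.occupancy_through_time(maps, n_observed=4, bin_width=1.0)
        sums = prof.groupby("bin_start")["mean"].sum()
        assert np.allclose(sums, 1.0, atol=1e-10)

    def test_empty_maps_error(self):
        with pytest.raises(ValueError):
            dc.occupancy_through_time([])

    def test_late_invasion_monotone_rise(self):
        # time-aware forward simulation: transitions into state 1 switched
        # on in the last 8 Myr only; mean state-1 occupancy must rise
        # toward the present
        tree = syn.simulate_bd_tree(80, 0.35, 0.0, seed=30)
        ages = tree.node_ages()
        rng = np.random.default_rng(31)
        reps = []
        for _ in range(30):
            states = np.zeros(tree.n_nodes, dtype=int)
            segs = {}
            for node in tree.preorder:
                p = tree.parent[node]
                if p < 0:
                    continue
                a_hi, a_lo = ages[p], ages[node]
                st = states[p]
                segments, t = [], a_hi
                while True:
                    rate = 0.4 if (st == 0 and t <= 8.0) else 0.0
                    dt = rng.exponential(1 / rate) if rate > 0 else np.inf
                    nxt = max(t - dt, a_lo) if dt < np.inf else a_lo
                    if t - dt <= a_lo:
                        segments.append((t - a_lo, st))
                        break
                    segments.append((dt, st))
                    t -= dt
                    st = 1
                _ = nxt
                states[node] = st
                segs[node] = segments
            reps.append(BranchHistory(tree=tree, segments=segs,
                                      node_states=states, n_changes=0))
        prof = dc.occupancy_through_time(reps, n_observed=2, bin_width=1.0)
        s1 = prof[prof.state == 1].sort_values("bin_start")["mean"].to_numpy()
        last = s1[:8][::-1]  # oldest-to-youngest over the last 8 Myr
        # require a rising trend block-averaged over pairs of bins
        blocks = last.reshape(4, 2).mean(axis=1)
        assert np.all(np.diff(blocks) > 0)
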