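import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from charsat.mk import (
    MkModelSpec,
    akaike_weights,
    fit_mk,
    marginal_ancestral_states,
    mk_loglik,
    model_comparison_table,
    paint_regimes,
    simulate_mk,
)
from charsat.mk import _edge_data
from charsat.trees import read_annotated_tree

from charsat import synthetic as syn


def enumeration_loglik(tree, trait, spec, rates):
    """Brute-force oracle: sum over all internal-node state assignments."""
    Pmap = _edge_data(tree, spec, rates)
    internals = [nd for nd in tree.tree.preorder_node_iter() if not nd.is_leaf()]
    n = spec.n_states
    total = 0.0
    for assign in itertools.product(range(n), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        p = 1.0 / n
        for nd in tree.tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            s_par = amap[nd.parent_node]
            s = trait[nd.taxon.label] if nd.is_leaf() else amap[nd]
            p *= Pmap[nd][s_par, s]
        total += p
    return np.log(total)


def random_tree(rng, n_tips):
    """Random bifurcating newick with uniform branch lengths."""
    parts = [f"T{i}:{rng.uniform(0.5, 5):.3f}" for i in range(n_tips)]
    while len(parts) > 2:
        i, j = sorted(rng.choice(len(parts), 2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.uniform(0.5, 5):.3f}")
    newick = f"({parts[0]},{parts[1]});"
    return read_annotated_tree(data=newick, root_age=100)


class TestLoglik:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 30), st.integers(3, 5), st.integers(2, 3),
           st.sampled_from(["ER", "ARD"]))
    def test_matches_enumeration_oracle(self, seed, n_tips, n_states, param):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, n_tips)
        spec = MkModelSpec(n_states, param)
        rates = rng.uniform(0.005, 0.5, spec.k)
        trait = {f"T{i}": int(rng.integers(0, n_states)) for i in range(n_tips)}
        ll = mk_loglik(tree, trait, spec, rates)
        oracle = enumeration_loglik(tree, trait, spec, rates)
        assert ll == pytest.approx(oracle, abs=1e-9)

    def test_zero_length_limit(self):
        tree = read_annotated_tree(data="(A:0,B:0);", root_age=0)
        ll = mk_loglik(tree, {"A": 0, "B": 0}, MkModelSpec(3, "ER"), [0.5])
        assert ll == pytest.approx(np.log(1 / 3), abs=1e-10)

    def test_two_state_closed_form(self):
        t, q = 2.0, 0.13
        tree = read_annotated_tree(data=f"(A:{t},B:{t});", root_age=t)
        ll = mk_loglik(tree, {"A": 0, "B": 1}, MkModelSpec(2, "ER"), [q])
        p_diff = 0.5 * (1 - np.exp(-2 * q * t))
        p_same = 0.5 * (1 + np.exp(-2 * q * t))
        closed = np.log(0.5 * 2 * p_same * p_diff)
        assert ll == pytest.approx(closed, abs=1e-10)

    def test_rerooting_invariance_under_er(self):
        rng = np.random.default_rng(5)
        newick = "((A:2,B:3):1.5,(C:1,D:4):2.5);"
        rerooted = "(((C:1,D:4):4.0,(A:2,B:3)):0.0);"  # same unrooted tree
        spec = MkModelSpec(3, "ER")
        trait = {"A": 0, "B": 1, "C": 2, "D": 0}
        ll1 = mk_loglik(read_annotated_tree(data=newick, root_age=10), trait, spec, [0.08])
        ll2 = mk_loglik(read_annotated_tree(data=rerooted, root_age=10), trait, spec, [0.08])
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_negative_rates_rejected(self):
        tree = read_annotated_tree(data="(A:1,B:1);", root_age=1)
        with pytest.raises(ValueError):
            mk_loglik(tree, {"A": 0, "B": 0}, MkModelSpec(2, "ER"), [-0.1])


class TestFit:
    def test_er_rate_recovery(self):
        sc = syn.SyntheticScenario(seed=13, tree=syn.TreeConfig(n_tips=200))
        tt = syn.simulate_tree(sc)
        spec = MkModelSpec(3, "ER")
        q_true = 0.02
        sim = simulate_mk(tt, spec, [q_true], seed=2)
        fit = fit_mk(tt, sim.tip_states, spec, n_starts=3, seed=1)
        assert fit.converged
        assert fit.rates[0] == pytest.approx(q_true, rel=0.5)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)

    def test_degenerate_regime_painting_matches_single_regime(self, quartet_time_tree):
        trait = {"A": 0, "B": 1, "C": 1, "D": 0}
        single = fit_mk(quartet_time_tree, trait, MkModelSpec(2, "ER"), seed=0)
        painting = {nd.node_id: 0 for nd in quartet_time_tree.branches()}
        painted = fit_mk(quartet_time_tree, trait,
                         MkModelSpec(2, "ER", n_regimes=1, regime_of=painting), seed=0)
        assert painted.loglik == pytest.approx(single.loglik, abs=1e-6)

    def test_invariant_trait_hits_zero_boundary(self, quartet_time_tree):
        trait = {t: 0 for t in "ABCD"}
        fit = fit_mk(quartet_time_tree, trait, MkModelSpec(2, "ER"), seed=0)
        assert fit.at_bound
        assert fit.rates[0] <= 1e-6

    def test_forced_equal_regimes_reproduce_single_regime_loglik(self):
        sc = syn.SyntheticScenario(seed=17, tree=syn.TreeConfig(n_tips=40))
        tt = syn.simulate_tree(sc)
        spec = MkModelSpec(3, "ER")
        sim = simulate_mk(tt, spec, [0.03], seed=3)
        single = fit_mk(tt, sim.tip_states, spec, n_starts=3, seed=1)
        painting = paint_regimes(tt, syn.assign_clades(tt), ["Synapsida", "Reptilia"])
        multi_spec = MkModelSpec(3, "ER", n_regimes=2, regime_of=painting)
        ll_forced = mk_loglik(tt, sim.tip_states, multi_spec,
                              np.tile(single.rates, 2))
        assert ll_forced == pytest.approx(single.loglik, abs=1e-8)


class TestAkaikeWeights:
    def test_closed_forms(self):
        w = akaike_weights([10.0, 10.0])
        assert np.allclose(w, [0.5, 0.5])
        w = akaike_weights([0.0, 20.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-10)))
        assert w[1] == pytest.approx(np.exp(-10) / (1 + np.exp(-10)))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 500), min_size=2, max_size=6),
           st.floats(-100, 100))
    def test_sums_to_one_and_shift_invariant(self, aics, shift):
        w = akaike_weights(aics)
        assert np.sum(w) == pytest.approx(1.0)
        assert np.allclose(w, akaike_weights(np.asarray(aics) + shift))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([1.0, np.inf])

    def test_comparison_table_weights(self):
        class F:
            def __init__(self, ll, k):
                self.loglik, self.k, self.aic = ll, k, 2 * k - 2 * ll
        tab = model_comparison_table({"a": F(-10, 1), "b": F(-9, 2)})
        assert tab["akaike_weight"].sum() == pytest.approx(1.0)


class TestAncestralStates:
    def test_two_tip_root_matches_bayes_closed_form(self):
        t, q = 1.5, 0.2
        tree = read_annotated_tree(data=f"(A:{t},B:{t});", root_age=t)
        spec = MkModelSpec(2, "ER")
        asr = marginal_ancestral_states(tree, {"A": 0, "B": 0}, spec, [q])
        p_same = 0.5 * (1 + np.exp(-2 * q * t))
        p_diff = 0.5 * (1 - np.exp(-2 * q * t))
        expect0 = p_same ** 2 / (p_same ** 2 + p_diff ** 2)
        root_id = tree.tree.seed_node.node_id
        assert asr[root_id][0] == pytest.approx(expect0, abs=1e-10)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 30))
    def test_matches_enumeration_oracle_on_quartets(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, 4)
        spec = MkModelSpec(3, "ER")
        rates = [float(rng.uniform(0.02, 0.3))]
        trait = {f"T{i}": int(rng.integers(0, 3)) for i in range(4)}
        asr = marginal_ancestral_states(tree, trait, spec, rates)
        # oracle: enumerate assignments, accumulate joint probability per node
        Pmap = _edge_data(tree, spec, np.asarray(rates))
        internals = [nd for nd in tree.tree.preorder_node_iter() if not nd.is_leaf()]
        post = {nd.node_id: np.zeros(3) for nd in internals}
        for assign in itertools.product(range(3), repeat=len(internals)):
            amap = dict(zip(internals, assign))
            p = 1.0 / 3
            for nd in tree.tree.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                s = trait[nd.taxon.label] if nd.is_leaf() else amap[nd]
                p *= Pmap[nd][amap[nd.parent_node], s]
            for nd in internals:
                post[nd.node_id][amap[nd]] += p
        for nid, vec in post.items():
            assert np.allclose(asr[nid], vec / vec.sum(), atol=1e-9)

    def test_probabilities_sum_to_one(self, quartet_time_tree):
        spec = MkModelSpec(4, "ARD")
        rng = np.random.default_rng(2)
        asr = marginal_ancestral_states(
            quartet_time_tree, {"A": 0, "B": 2, "C": 3, "D": 1}, spec,
            rng.uniform(0.01, 0.2, spec.k))
        for vec in asr.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)


class TestSimulation:
    def test_zero_rates_keep_root_state(self, quartet_time_tree):
        spec = MkModelSpec(3, "ER")
        sim = simulate_mk(quartet_time_tree, spec, [0.0], root_state=2, seed=1)
        assert set(sim.tip_states.values()) == {2}
        assert all(n == 0 for n in sim.n_changes.values())

    def test_high_rate_long_tree_near_uniform(self):
        sc = syn.SyntheticScenario(seed=19, tree=syn.TreeConfig(n_tips=300))
        tt = syn.simulate_tree(sc)
        spec = MkModelSpec(2, "ER")
        sim = simulate_mk(tt, spec, [1.0], root_state=0, seed=4)
        freq = np.mean([s for s in sim.tip_states.values()])
        assert freq == pytest.approx(0.5, abs=0.08)

    def test_upper_triangular_regime_never_decreases(self):
        sc = syn.SyntheticScenario(seed=23, tree=syn.TreeConfig(n_tips=80))
        tt = syn.simulate_tree(sc)
        groups = syn.assign_clades(tt)
        table, spec, truth = syn.simulate_size_dataset(tt, sc, tip_groups=groups)
        order = {s: i for i, s in enumerate(spec.state_order)}
        # along every branch in the no-decrease regime, state is monotone
        for nd in tt.branches():
            if spec.regime(nd.node_id) != 0:  # regime 0 = mammal-line
                continue
            parent_state = truth.trait_history[nd.parent_node.node_id]
            child_state = truth.trait_history[nd.node_id]
            assert child_state >= parent_state

    def test_reproducible_under_seed(self, quartet_time_tree):
        spec = MkModelSpec(4, "ARD")
        rng = np.random.default_rng(0)
        rates = rng.uniform(0.01, 0.3, spec.k)
        a = simulate_mk(quartet_time_tree, spec, rates, seed=11)
        b = simulate_mk(quartet_time_tree, spec, rates, seed=11)
        assert a.tip_states == b.tip_states and a.node_states == b.node_states
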