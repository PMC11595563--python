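"""Mk likelihoods and marginal reconstructions against enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from phylosdm.ancestral import (MkModel, fit_mk, marginal_states, mk_loglik,
                                read_tip_states, select_model)
from phylosdm.phylo import TimeTree
from phylosdm.synthetic import sim_mk_tip_states, sim_yule_tree


def enumerate_likelihood(tree, tip_states, model):
    """Oracle: sum the joint probability over every assignment of states
    to internal nodes (uniform root prior)."""
    k = model.k
    internals = list(tree.dtree.preorder_internal_node_iter())
    P = {nd: expm(model.Q * (nd.edge.length or 0.0))
         for nd in tree.dtree.preorder_node_iter()
         if nd.parent_node is not None}
    total = 0.0
    node_marg = {nd: np.zeros(k) for nd in internals}
    tip_marg = {nd: np.zeros(k) for nd in tree.dtree.leaf_node_iter()}
    tip_sets = {}
    for leaf in tree.dtree.leaf_node_iter():
        s = tip_states[leaf.taxon.label]
        tip_sets[leaf] = list(s) if isinstance(s, (set, frozenset)) else [s]
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        for tip_choice in itertools.product(*[tip_sets[lf] for lf in
                                              tree.dtree.leaf_node_iter()]):
            tmap = dict(zip(tree.dtree.leaf_node_iter(), tip_choice))
            prob = 1.0 / k  # uniform root prior
            for nd in tree.dtree.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                parent_s = amap[nd.parent_node]
                s = amap[nd] if nd in amap else tmap[nd]
                prob *= P[nd][parent_s, s]
            total += prob
            for nd, s in amap.items():
                node_marg[nd][s] += prob
            for nd, s in tmap.items():
                tip_marg[nd][s] += prob
    marg = {}
    for nd in internals:
        marg[nd] = node_marg[nd] / total
    for nd in tip_marg:
        marg[nd] = tip_marg[nd] / total
    return np.log(total), marg


class TestMkModel:
    def test_rate_matrix_shapes_and_row_sums(self):
        for scheme, n in (("ER", 1), ("SYM", 6), ("ARD", 12)):
            m = MkModel(4, scheme, np.linspace(0.1, 0.5, n))
            Q = m.Q
            np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            assert (Q - np.diag(np.diag(Q)) >= 0).all()

    def test_transition_matrix_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = MkModel(4, "ARD", rng.uniform(0.01, 2.0, size=12))
            for t in (0.0, 0.5, 5.0, 80.0):
                P = expm(m.Q * t)
                np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_two_state_closed_form(self):
        # ER with k=2: P(stay) = 1/2 + 1/2 e^{-2qt}
        q, t = 0.37, 1.9
        P = expm(MkModel(2, "ER", [q]).Q * t)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * np.exp(-2 * q * t),
                                        abs=1e-12)
        assert P[0, 1] == pytest.approx(0.5 - 0.5 * np.exp(-2 * q * t),
                                        abs=1e-12)


class TestLikelihood:
    def test_zero_rate_identical_tips_give_uniform_root_likelihood(self):
        tree = TimeTree.from_newick("((A:1,B:1):1,C:2);")
        m = MkModel(3, "ER", [1e-12])
        ll = mk_loglik(tree, {"A": 0, "B": 0, "C": 0}, m)
        assert ll == pytest.approx(-np.log(3), abs=1e-6)

    def test_three_tip_tree_matches_enumeration(self):
        tree = TimeTree.from_newick("((A:1,B:1):1,C:2);")
        m = MkModel(2, "ER", [0.4])
        states = {"A": 0, "B": 0, "C": 1}
        want, _ = enumerate_likelihood(tree, states, m)
        assert mk_loglik(tree, states, m) == pytest.approx(want, abs=1e-10)

    def test_random_trees_match_enumeration(self):
        rng = np.random.default_rng(30)
        for trial in range(12):
            n_tips = int(rng.integers(3, 7))       # <= 6 tips
            k = int(rng.integers(2, 5))            # <= 4 states
            tree = sim_yule_tree(n_tips, 0.7, seed=300 + trial)
            scheme = ["ER", "SYM", "ARD"][trial % 3]
            rates = rng.uniform(0.05, 1.0,
                                size=MkModel.n_params(k, scheme))
            model = MkModel(k, scheme, rates)
            states = {t: int(rng.integers(k)) for t in tree.tip_labels}
            if trial % 4 == 0:  # exercise ambiguity sets too
                first = tree.tip_labels[0]
                states[first] = frozenset({0, min(1, k - 1)})
            want_ll, want_marg = enumerate_likelihood(tree, states, model)
            assert mk_loglik(tree, states, model) == pytest.approx(
                want_ll, abs=1e-10)
            recon = marginal_states(tree, states, model)
            got = {lbl: p for lbl, p in zip(recon.node_labels,
                                            recon.node_probs)}
            want_by_label = {}
            i_int = 0
            for nd in tree.dtree.preorder_node_iter():
                if nd.is_leaf():
                    want_by_label[nd.taxon.label] = want_marg[nd]
                else:
                    want_by_label[f"node{i_int}"] = want_marg[nd]
                    i_int += 1
            for lbl, p in got.items():
                np.testing.assert_allclose(p, want_by_label[lbl],
                                           atol=1e-10)

    def test_tip_ordering_invariance(self):
        tree_a = TimeTree.from_newick("((A:1,B:1):1,C:2);")
        tree_b = TimeTree.from_newick("(C:2,(B:1,A:1):1);")
        m = MkModel(2, "ER", [0.3])
        states = {"A": 0, "B": 1, "C": 1}
        assert mk_loglik(tree_a, states, m) == pytest.approx(
            mk_loglik(tree_b, states, m), abs=1e-12)


class TestMarginals:
    def test_observed_tip_gets_probability_one(self):
        tree = sim_yule_tree(8, 0.5, seed=31)
        states = {t: i % 3 for i, t in enumerate(tree.tip_labels)}
        recon = marginal_states(tree, states, MkModel(3, "ER", [0.2]))
        for lbl, leaf, p in zip(recon.node_labels, recon.node_is_leaf,
                                recon.node_probs):
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            if leaf:
                assert p[states[lbl]] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_tips_make_internal_modal_state_match(self):
        tree = sim_yule_tree(10, 0.5, seed=32)
        states = {t: 2 for t in tree.tip_labels}
        recon = marginal_states(tree, states, MkModel(3, "ER", [0.1]))
        for p, leaf in zip(recon.node_probs, recon.node_is_leaf):
            if not leaf:
                assert int(np.argmax(p)) == 2


class TestFitting:
    def test_all_identical_tips_hit_lower_bound(self):
        tree = sim_yule_tree(10, 0.5, seed=33)
        with pytest.warns(UserWarning, match="lower boundary"):
            model, _ = fit_mk(tree, {t: 1 for t in tree.tip_labels}, "ER")
        assert model.rates[0] == pytest.approx(1e-8)

    def test_ard_loglik_never_below_er(self):
        tree = sim_yule_tree(25, 0.4, seed=34).rescale(20.0)
        states = sim_mk_tip_states(tree, 3, 0.05, seed=35)
        _, ll_er = fit_mk(tree, states, "ER")
        _, ll_ard = fit_mk(tree, states, "ARD")
        assert ll_ard >= ll_er - 1e-6

    def test_root_area_recovered_from_planted_history(self):
        # deep-rooted history with slow dispersal: the reconstruction
        # should identify the true root area in >= 80% of replicates
        hits, attempts = 0, 0
        for rep in range(20):
            tree = sim_yule_tree(60, 0.4, seed=600 + rep).rescale(60.0)
            states, true_root = sim_mk_tip_states(tree, 4, 0.002,
                                                  seed=700 + rep,
                                                  with_root=True)
            if len(set(states.values())) < 2:
                continue
            attempts += 1
            model, _ = fit_mk(tree, states, "ER")
            recon = marginal_states(tree, states, model)
            hits += recon.modal_states[0] == true_root
        assert attempts >= 10
        assert hits / attempts >= 0.8


class TestSelection:
    def test_aic_prefers_parsimonious_near_tie(self):
        er = MkModel(4, "ER", [0.1])
        ard = MkModel(4, "ARD", np.full(12, 0.1))
        # AIC: ER = 2*1 + 20 = 22, ARD = 2*12 + 19.8 = 43.8
        assert select_model([(er, -10.0), (ard, -9.9)], "aic") == "ER"
        assert select_model([(er, -10.0), (ard, -9.9)], "loglik") == "ARD"

    def test_single_fit_returned(self):
        er = MkModel(2, "ER", [0.5])
        assert select_model([(er, -3.0)]) == "ER"

    def test_er_data_selects_er_under_aic(self):
        wins = 0
        for rep in range(10):
            tree = sim_yule_tree(100, 0.4, seed=800 + rep).rescale(40.0)
            states = sim_mk_tip_states(tree, 3, 0.03, seed=900 + rep)
            if len(set(states.values())) < 2:
                continue
            fits = [fit_mk(tree, states, s) for s in ("ER", "SYM", "ARD")]
            wins += select_model([(m, ll) for m, ll in fits], "aic") == "ER"
        assert wins >= 9


def test_tip_state_tsv_parsing(tmp_path):
    path = tmp_path / "areas.tsv"
    path.write_text("sp1\tSE\nsp2\tSE|SW\nout1\tNull\n")
    states, prune = read_tip_states(path)
    assert states["sp1"] == 2
    assert states["sp2"] == frozenset({2, 3})
    assert prune == ["out1"]
    path.write_text("sp1\tXX\n")
    with pytest.raises(ValueError, match="unknown area"):
        read_tip_states(path)
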