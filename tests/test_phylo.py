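"""Substitution models, pruning likelihood, distances, NJ, branch lengths."""

import itertools
import math

import numpy as np
import pytest

from bitterevo.formats import SequenceSet
from bitterevo.phylo import (AMINO_ACIDS, PhyloTree, SubstModel, log_likelihood,
                             nj_tree, optimize_branch_lengths, pairwise_distance,
                             poisson_model, robinson_foulds)
from bitterevo.synthetic import SimConfig, random_tree, simulate_protein


def closed_form_p_same(t, n=20):
    return 1.0 / n + (n - 1.0) / n * math.exp(-n / (n - 1.0) * t)


class TestNewick:
    def test_two_leaf_parse(self):
        t = PhyloTree.from_newick("(a:0.1,b:0.2);")
        lengths = {n.label: n.length for n in t.leaves}
        assert lengths == {"a": 0.1, "b": 0.2}

    def test_internal_label_retained(self):
        t = PhyloTree.from_newick("((a:1,b:1)N2:1,c:2);")
        assert any(n.label == "N2" for n in t.postorder() if not n.is_leaf)
        assert "N2" in t.to_newick()

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            PhyloTree.from_newick("(a:-0.1,b:0.2);")

    def test_round_trip_random_trees(self):
        for seed in range(5):
            t = random_tree(10, seed=seed)
            back = PhyloTree.from_newick(t.to_newick())
            assert robinson_foulds(t, back) == 0
            orig = {n.label: n.length for n in t.leaves}
            new = {n.label: n.length for n in back.leaves}
            assert new == pytest.approx(orig, rel=1e-10)

    def test_branch_length_precision(self):
        t = PhyloTree.from_newick("(a:0.123456789012,b:1e-7);")
        back = PhyloTree.from_newick(t.to_newick())
        lengths = {n.label: n.length for n in back.leaves}
        assert lengths["a"] == pytest.approx(0.123456789012, rel=1e-10)
        assert lengths["b"] == pytest.approx(1e-7, rel=1e-10)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, poisson):
        assert np.allclose(poisson.transition_matrix(0.0), np.eye(20), atol=1e-12)

    def test_rows_sum_to_one(self, jtt):
        for t in (0.01, 0.5, 3.0):
            P = jtt.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_poisson_closed_form(self, poisson):
        # frozen from the equal-rate equal-frequency closed form
        P = poisson.transition_matrix(0.5)
        assert P[0, 0] == pytest.approx(closed_form_p_same(0.5), abs=1e-10)
        assert P[0, 0] == pytest.approx(0.61124, abs=5e-6)

    def test_chapman_kolmogorov(self, jtt, rng):
        for _ in range(3):
            t1, t2 = rng.uniform(0.01, 1.0, size=2)
            lhs = jtt.transition_matrix(t1) @ jtt.transition_matrix(t2)
            rhs = jtt.transition_matrix(t1 + t2)
            assert np.abs(lhs - rhs).max() < 1e-8

    def test_detailed_balance(self, jtt):
        Q = jtt.rate_matrix
        pi = jtt.frequencies
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)

    def test_negative_time_rejected(self, jtt):
        with pytest.raises(ValueError):
            jtt.transition_matrix(-0.1)


class TestLikelihood:
    def test_two_identical_single_residue_leaves(self, poisson):
        msa = SequenceSet([("x", "A"), ("y", "A")], aligned=True)
        tree = PhyloTree.from_newick("(x:0.25,y:0.25);")
        expected = math.log((1 / 20) * closed_form_p_same(0.5))
        assert log_likelihood(tree, msa, poisson) == pytest.approx(expected, abs=1e-10)

    def test_zero_branch_identical_leaves(self, poisson):
        msa = SequenceSet([("x", "A"), ("y", "A")], aligned=True)
        tree = PhyloTree.from_newick("(x:0,y:0);")
        assert log_likelihood(tree, msa, poisson) == pytest.approx(-math.log(20), abs=1e-12)

    def test_pruning_matches_enumeration(self, jtt):
        tree = PhyloTree.from_newick("((a:0.3,b:0.5):0.2,(c:0.7,d:0.1):0.4);")
        msa = SequenceSet([("a", "ACW"), ("b", "ADW"), ("c", "CC-"), ("d", "ACY")],
                          aligned=True)
        got = log_likelihood(tree, msa, jtt)
        idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
        P = {t: jtt.transition_matrix(t) for t in (0.3, 0.5, 0.2, 0.7, 0.1, 0.4)}
        pi = jtt.frequencies
        total = 0.0
        for site in range(3):
            obs = {l: msa.get(l)[site] for l in "abcd"}
            site_l = 0.0
            for x, y in itertools.product(range(20), repeat=2):
                term = (pi * P[0.2][:, x] * P[0.4][:, y]).sum()
                for leaf, t, anc in (("a", 0.3, x), ("b", 0.5, x),
                                     ("c", 0.7, y), ("d", 0.1, y)):
                    s = obs[leaf]
                    term *= 1.0 if s == "-" else P[t][anc, idx[s]]
                site_l += term
            total += math.log(site_l)
        assert got == pytest.approx(total, abs=1e-9)

    def test_invariant_to_rerooting(self, jtt):
        tree = PhyloTree.from_newick("((a:1,b:2):0.5,(c:3,(d:4,e:1):0.5):0.5);")
        msa = SequenceSet([("a", "AC"), ("b", "CC"), ("c", "AD"),
                           ("d", "WY"), ("e", "AC")], aligned=True)
        base = log_likelihood(tree, msa, jtt)
        for og in (["a"], ["d", "e"], ["c"]):
            rerooted = tree.root_with_outgroup(og)
            assert log_likelihood(rerooted, msa, jtt) == pytest.approx(base, abs=1e-8)

    def test_missing_leaf_reported_by_name(self, jtt):
        tree = PhyloTree.from_newick("(a:1,missing_taxon:1);")
        msa = SequenceSet([("a", "AC")], aligned=True)
        with pytest.raises(ValueError, match="missing_taxon"):
            log_likelihood(tree, msa, jtt)

    def test_one_gamma_category_equals_no_gamma(self):
        m_plain = poisson_model()
        m_g1 = poisson_model(gamma_shape=0.5, n_rate_categories=1)
        msa = SequenceSet([("a", "ACDEF"), ("b", "ACDEW"), ("c", "ACYEF")],
                          aligned=True)
        tree = PhyloTree.from_newick("((a:0.2,b:0.3):0.1,c:0.4);")
        assert log_likelihood(tree, msa, m_g1) == pytest.approx(
            log_likelihood(tree, msa, m_plain), abs=1e-10)


class TestPairwiseDistance:
    def test_identical_sequences(self, poisson):
        assert pairwise_distance("ACDEF", "ACDEF", poisson) == 0.0

    def test_half_different_closed_form(self, poisson):
        a = "A" * 50 + "C" * 50
        b = "A" * 50 + "D" * 50
        # -(19/20) ln(1 - (20/19) 0.5), frozen
        assert pairwise_distance(a, b, poisson) == pytest.approx(0.709853, abs=1e-6)

    def test_ml_matches_closed_form(self, poisson):
        equal_rates_ml = SubstModel(
            kind="empirical",
            exchangeability=np.ones((20, 20)) - np.eye(20),
            frequencies=np.full(20, 1 / 20),
        )
        a = "A" * 60 + "C" * 40
        b = "A" * 60 + "D" * 40
        d_closed = pairwise_distance(a, b, poisson)
        d_ml = pairwise_distance(a, b, equal_rates_ml)
        assert d_ml == pytest.approx(d_closed, abs=1e-6)

    def test_saturation_returns_dmax(self, poisson):
        a = "ACDEFGHIKLMNPQRSTVWY"
        b = "CDEFGHIKLMNPQRSTVWYA"
        assert pairwise_distance(a, b, poisson, d_max=7.5) == 7.5


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # distances from ((a:1,b:2):1,(c:3,d:4));
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = nj_tree(D, ["a", "b", "c", "d"])
        truth = PhyloTree.from_newick("((a:1,b:2):1,(c:3,d:4));")
        assert robinson_foulds(tree, truth) == 0
        # additive matrix: path lengths reproduce D exactly
        assert _path_length(tree, "a", "b") == pytest.approx(3.0)
        assert _path_length(tree, "a", "c") == pytest.approx(5.0)
        assert _path_length(tree, "c", "d") == pytest.approx(7.0)

    def test_three_taxon_closed_form(self):
        # d(a,b)=3, d(a,c)=4, d(b,c)=5 -> a:1, b:2, c:3
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {n.label: n.length for n in tree.leaves}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D, ["a", "b", "c"])


def _path_length(tree, a, b):
    def to_root(label):
        node = tree.find(label)
        path = {}
        d = 0.0
        while node is not None:
            path[id(node)] = d
            d += node.length or 0.0
            node = node.parent
        return path

    pa, pb = to_root(a), to_root(b)
    node = tree.find(b)
    d = 0.0
    while id(node) not in pa:
        d += node.length or 0.0
        node = node.parent
    return d + pa[id(node)]


class TestBranchOptimization:
    def test_two_sequence_equals_ml_distance(self, poisson):
        a = "A" * 60 + "C" * 40
        b = "A" * 60 + "D" * 40
        msa = SequenceSet([("x", a), ("y", b)], aligned=True)
        tree = PhyloTree.from_newick("(x:0.1,y:0.1);")
        opt = optimize_branch_lengths(tree, msa, poisson)
        total = sum(n.length for n in opt.postorder() if n.parent is not None)
        assert total == pytest.approx(pairwise_distance(a, b, poisson), abs=1e-4)

    def test_loglik_non_decreasing_and_fixed_point(self, jtt):
        tree = random_tree(6, seed=4, mean_branch=0.2)
        msa, _ = simulate_protein(SimConfig(tree=tree, n_sites=200, seed=4, model=jtt))
        from bitterevo.phylo import log_likelihood
        before = log_likelihood(tree, msa, jtt)
        opt = optimize_branch_lengths(tree, msa, jtt, tol=1e-4)
        after = log_likelihood(opt, msa, jtt)
        assert after >= before - 1e-9
        again = optimize_branch_lengths(opt, msa, jtt, tol=1e-4, max_sweeps=1)
        assert log_likelihood(again, msa, jtt) == pytest.approx(after, abs=1e-2)

    def test_recovers_simulated_lengths(self, jtt):
        tree = random_tree(8, seed=9, mean_branch=0.15)
        msa, _ = simulate_protein(SimConfig(tree=tree, n_sites=5000, seed=9, model=jtt))
        start = tree.copy()
        for node in start.postorder():
            if node.parent is not None:
                node.length = 0.1
        opt = optimize_branch_lengths(start, msa, jtt, tol=1e-3)
        # the two root-child branch lengths are only identifiable as a sum
        root_children_true = {id(c) for c in tree.root.children}

        def summarize(t):
            branches = {}
            root_sum = 0.0
            for n in t.postorder():
                if n.parent is None:
                    continue
                if n.parent is t.root:
                    root_sum += n.length
                else:
                    branches[n.index] = n.length
            return branches, root_sum

        truth, truth_root = summarize(tree)
        est, est_root = summarize(opt)
        assert est_root == pytest.approx(truth_root, rel=0.15)
        for key, t_true in truth.items():
            if t_true < 0.02:  # relative error meaningless for tiny branches
                continue
            assert est[key] == pytest.approx(t_true, rel=0.15)
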