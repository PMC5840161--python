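"""Marginal and joint ancestral reconstruction, and key-residue extraction."""

import itertools
import math

import numpy as np
import pytest

from bitterevo.ancestral import extract_key_residues, joint_asr, marginal_asr
from bitterevo.formats import SequenceSet, map_bw_numbers
from bitterevo.phylo import AMINO_ACIDS, PhyloTree
from bitterevo.synthetic import SimConfig, balanced_tree, simulate_protein


@pytest.fixture(scope="module")
def four_taxon_case(request):
    tree = PhyloTree.from_newick("((a:0.3,b:0.5)X:0.2,(c:0.7,d:0.1)Y:0.4)R;")
    msa = SequenceSet([("a", "ACWQ"), ("b", "ADWQ"), ("c", "CC-H"), ("d", "ACYH")],
                      aligned=True)
    return tree, msa


def brute_force_posteriors_and_argmax(tree_lengths, msa, model):
    """Enumeration oracle over both internal states of the 4-taxon tree
    ((a,b)X,(c,d)Y)R with R==X's parent==Y's parent collapsed to two free
    internal nodes X, Y plus root R."""
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    P = {t: model.transition_matrix(t) for t in set(tree_lengths.values())}
    pi = model.frequencies
    n_sites = len(msa.records[0][1])
    posts, argmaxes = [], []
    for site in range(n_sites):
        obs = {l: msa.get(l)[site] for l in "abcd"}
        post = np.zeros((3, 20))
        best, best_l = None, -1.0
        total = 0.0
        for x, y, r in itertools.product(range(20), repeat=3):
            L = pi[r] * P[tree_lengths["X"]][r, x] * P[tree_lengths["Y"]][r, y]
            for leaf, anc in (("a", x), ("b", x), ("c", y), ("d", y)):
                s = obs[leaf]
                L *= 1.0 if s == "-" else P[tree_lengths[leaf]][anc, idx[s]]
            post[0, x] += L
            post[1, y] += L
            post[2, r] += L
            total += L
            if L > best_l:
                best_l, best = L, (x, y, r)
        posts.append(post / total)
        argmaxes.append(best)
    return posts, argmaxes


class TestMarginal:
    def test_matches_enumeration(self, four_taxon_case, jtt):
        tree, msa = four_taxon_case
        profile = marginal_asr(tree, msa, jtt)
        lengths = {"a": 0.3, "b": 0.5, "c": 0.7, "d": 0.1, "X": 0.2, "Y": 0.4}
        posts, _ = brute_force_posteriors_and_argmax(lengths, msa, jtt)
        for site in range(4):
            for k, lab in enumerate(("X", "Y", "R")):
                assert np.abs(profile.posterior[lab][site] - posts[site][k]).max() < 1e-9

    def test_posteriors_normalize(self, four_taxon_case, jtt):
        tree, msa = four_taxon_case
        profile = marginal_asr(tree, msa, jtt)
        for lab in profile.node_labels:
            assert np.allclose(profile.posterior[lab].sum(axis=1), 1.0, atol=1e-10)

    def test_star_limit_certainty(self, jtt):
        tree = PhyloTree.from_newick("((a:1e-9,b:1e-9)I:1e-9,(c:1e-9,d:1e-9)J:1e-9)R;")
        msa = SequenceSet([(l, "W") for l in "abcd"], aligned=True)
        profile = marginal_asr(tree, msa, jtt)
        w = AMINO_ACIDS.index("W")
        for lab in ("I", "J", "R"):
            assert profile.posterior[lab][0][w] > 0.9999

    def test_root_posterior_equals_clamped_likelihood_ratio(self, four_taxon_case, jtt):
        # direct identity: posterior(root=a) = pi_a * L(data | root=a) / L(data)
        tree, msa = four_taxon_case
        profile = marginal_asr(tree, msa, jtt)
        from bitterevo.phylo import _PruningWorkspace
        ws = _PruningWorkspace(tree, msa, jtt)
        partials, logscale = ws.up_pass(1.0)
        root_partial = partials[ws.nodes[-1].index]
        expected = root_partial * jtt.frequencies[None, :]
        expected /= expected.sum(axis=1, keepdims=True)
        assert np.abs(profile.posterior["R"] - expected[ws.site_to_pat]).max() < 1e-10

    def test_unrooted_tree_rejected(self, jtt):
        tree = PhyloTree.from_newick("(a:1,b:1,c:1);")
        msa = SequenceSet([(l, "A") for l in "abc"], aligned=True)
        with pytest.raises(ValueError, match="root"):
            marginal_asr(tree, msa, jtt)


class TestJoint:
    def test_matches_enumeration(self, four_taxon_case, jtt):
        tree, msa = four_taxon_case
        joint = joint_asr(tree, msa, jtt)
        lengths = {"a": 0.3, "b": 0.5, "c": 0.7, "d": 0.1, "X": 0.2, "Y": 0.4}
        _, argmaxes = brute_force_posteriors_and_argmax(lengths, msa, jtt)
        for site, (x, y, r) in enumerate(argmaxes):
            assert joint["X"][site] == AMINO_ACIDS[x]
            assert joint["Y"][site] == AMINO_ACIDS[y]
            assert joint["R"][site] == AMINO_ACIDS[r]

    def test_zero_branches_identical_leaves(self, jtt):
        tree = PhyloTree.from_newick("((a:0,b:0)I:0,(c:0,d:0)J:0)R;")
        msa = SequenceSet([(l, "KW") for l in "abcd"], aligned=True)
        joint = joint_asr(tree, msa, jtt)
        assert joint == {"I": "KW", "J": "KW", "R": "KW"}


@pytest.fixture(scope="module")
def sim(jtt):
    tree = balanced_tree(16, branch_length=0.06)
    msa, truth = simulate_protein(SimConfig(tree=tree, n_sites=1000, seed=202,
                                            model=jtt))
    profile = marginal_asr(tree, msa, jtt)
    joint = joint_asr(tree, msa, jtt)
    return tree, msa, truth, profile, joint


class TestSimulationCalibration:
    """Reconstruction quality on data simulated under the same (JTT) model."""

    def test_high_confidence_map_calls_accurate(self, sim):
        _, _, truth, profile, _ = sim
        correct = total = 0
        for lab in profile.node_labels:
            post = profile.posterior[lab]
            conf = post.max(axis=1)
            calls = post.argmax(axis=1)
            true_seq = truth[lab]
            for site in np.nonzero(conf > 0.99)[0]:
                total += 1
                correct += AMINO_ACIDS[calls[site]] == true_seq[site]
        assert total > 2000
        assert correct / total >= 0.99

    def test_posterior_calibration_by_decile(self, sim):
        _, _, truth, profile, _ = sim
        confs, hits = [], []
        for lab in profile.node_labels:
            post = profile.posterior[lab]
            conf = post.max(axis=1)
            calls = post.argmax(axis=1)
            true_seq = truth[lab]
            confs.extend(conf)
            hits.extend(AMINO_ACIDS[c] == true_seq[i] for i, c in enumerate(calls))
        confs, hits = np.array(confs), np.array(hits, dtype=float)
        assert len(confs) >= 5000
        for lo in np.arange(0.0, 1.0, 0.1):
            mask = (confs >= lo) & (confs < lo + 0.1)
            if mask.sum() < 100:  # skip sparsely populated deciles
                continue
            assert abs(hits[mask].mean() - confs[mask].mean()) < 0.05

    def test_joint_agrees_with_confident_marginal(self, sim):
        _, _, _, profile, joint = sim
        agree = total = 0
        for lab in profile.node_labels:
            post = profile.posterior[lab]
            conf = post.max(axis=1)
            calls = post.argmax(axis=1)
            for site in np.nonzero(conf > 0.99)[0]:
                total += 1
                agree += joint[lab][site] == AMINO_ACIDS[calls[site]]
        assert agree / total >= 0.99


class TestKeyResidueExtraction:
    def _receptor_msa(self):
        """A toy MSA whose reference carries W/Y/M at annotated positions,
        mirroring the tryptophan, tyrosine and methionine anchors of the
        T2R10 strychnine pocket."""
        ref = "AAAAWAAAAYAAAAM"     # W at 5, Y at 10, M at 15 (1-based)
        oth = "AAAAFAAAAYAAAAI"
        return SequenceSet([("hT2R10", ref), ("other", oth)], aligned=True)

    def test_extant_extraction(self):
        msa = self._receptor_msa()
        bw = map_bw_numbers(msa, "hT2R10", [(5, "3.32"), (10, "6.51"), (15, "7.39")])
        mat = extract_key_residues(msa, bw, ["3.32", "6.51", "7.39"])
        assert list(mat.residues.loc["hT2R10"]) == ["W", "Y", "M"]
        assert list(mat.residues.loc["other"]) == ["F", "Y", "I"]
        assert mat.posteriors.isna().all().all()

    def test_unresolvable_label_rejected(self):
        msa = self._receptor_msa()
        bw = map_bw_numbers(msa, "hT2R10", [(5, "3.32")])
        with pytest.raises(KeyError, match="7.43"):
            extract_key_residues(msa, bw, ["7.43"])

    def test_tie_reported_for_uniform_posterior(self, poisson):
        # two equidistant leaves with different residues under an exchange-
        # symmetric model: the two residues get exactly equal posteriors
        tree = PhyloTree.from_newick("(a:0.5,b:0.5)R;")
        msa = SequenceSet([("a", "LA"), ("b", "IA")], aligned=True)
        profile = marginal_asr(tree, msa, poisson)
        bw_msa = SequenceSet([("a", "LA"), ("b", "IA")], aligned=True)
        bw = map_bw_numbers(bw_msa, "a", [(1, "7.42")])
        mat = extract_key_residues(profile, bw, ["7.42"], tie_delta=0.05)
        call = mat.residues.loc["R", "7.42"]
        assert "/" in call
        assert set(call.split("/")) == {"L", "I"}
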