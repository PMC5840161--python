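"""Ancestral sequence reconstruction on a rooted phylogeny.

Two standard flavors are provided.  *Marginal* reconstruction computes, for
every internal node and alignment column, the posterior distribution over
states given the observed leaves (up/down message passing; the posterior at a
node is proportional to the product of the upward partial likelihood, the
downward message, and the equilibrium frequencies).  *Joint* reconstruction
finds the single most probable assignment of states to all internal nodes
simultaneously (max-product dynamic programming with backtracking).

With discrete-gamma rate variation, marginal posteriors are mixed across
rate categories weighted by each category's per-site responsibility; joint
reconstruction maximizes over (assignment, category) pairs per site.

Gaps are treated as missing data in the likelihood.  An internal node-site
is flagged as a gap when more than half of its descendant leaves are gapped
there (a parsimony-style majority rule); flagged sites are excluded from
residue calls.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import BWMap, SequenceSet
from .phylo import PhyloTree, SubstModel, TreeNode, _PruningWorkspace

DEFAULT_TIE_DELTA = 0.05


@dataclasses.dataclass
class AncestralProfile:
    """Per-node, per-column posterior summaries of a marginal reconstruction."""

    states: str | list[str]
    node_labels: list[str]
    n_sites: int
    posterior: dict[str, np.ndarray]        # label -> (n_sites, n_states)
    gap_flag: dict[str, np.ndarray]         # label -> (n_sites,) bool

    def __post_init__(self) -> None:
        for label, post in self.posterior.items():
            sums = post.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError(f"posteriors at node {label!r} do not normalize")

    def map_state(self, label: str, site: int) -> tuple[str, float]:
        """MAP state and its posterior probability at one node-site."""
        post = self.posterior[label][site]
        k = int(post.argmax())
        return self.states[k], float(post[k])

    def second_state(self, label: str, site: int) -> tuple[str, float]:
        post = self.posterior[label][site]
        order = np.argsort(post)[::-1]
        return self.states[int(order[1])], float(post[order[1]])

    def map_sequence(self, label: str, gap_char: str = "-") -> str:
        """MAP sequence for one node; gap-flagged sites emit ``gap_char``."""
        post = self.posterior[label]
        gaps = self.gap_flag[label]
        chars = [self.states[int(k)] for k in post.argmax(axis=1)]
        return "".join(gap_char if g else c for g, c in zip(gaps, chars))

    def map_posteriors(self, label: str) -> np.ndarray:
        return self.posterior[label].max(axis=1)


def _descendant_gap_fraction(tree: PhyloTree, msa: SequenceSet) -> dict[str, np.ndarray]:
    """Fraction of descendant leaves gapped at each site, per internal node."""
    n_sites = len(msa.records[0][1])
    gapped: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            seq = msa.get(node.label)
            gapped[node.index] = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("-")
            counts[node.index] = 1
        else:
            acc = np.zeros(n_sites)
            total = 0
            for c in node.children:
                acc = acc + gapped[c.index]
                total += counts[c.index]
            gapped[node.index] = acc
            counts[node.index] = total
            out[node.label] = acc / total > 0.5
    return out


def _require_rooted_labeled(tree: PhyloTree) -> None:
    if not tree.rooted:
        raise ValueError(
            "ancestral reconstruction requires a rooted tree; root it first, "
            "e.g. with PhyloTree.root_with_outgroup"
        )
    tree.label_internal_nodes()


def marginal_asr(tree: PhyloTree, msa: SequenceSet, model: SubstModel,
                 tokenizer=None) -> AncestralProfile:
    """Marginal reconstruction: per internal node and site, the posterior
    distribution over states given all leaf data.

    Unlabeled internal nodes are labeled in place by postorder number (N1,
    N2, ...).
    """
    _require_rooted_labeled(tree)
    ws = _PruningWorkspace(tree, msa, model, tokenizer)
    nodes = ws.nodes
    internal = [n for n in nodes if not n.is_leaf]
    n_states = model.n_states
    pi = model.frequencies

    # per-category per-pattern site log-likelihood -> category responsibilities
    n_cat = len(ws.rates)
    cat_post = {n.label: np.zeros((ws.n_pat, n_states)) for n in internal}
    per_cat_ll = np.empty((n_cat, ws.n_pat))
    per_cat_node_post: list[dict[str, np.ndarray]] = []

    for ci, rate in enumerate(ws.rates):
        partials, logscale = ws.up_pass(rate)
        # cache child messages M_c = U_c P_c^T for the down pass
        messages: dict[int, np.ndarray] = {}
        for node in nodes:
            if node.parent is not None:
                P = ws.transition(node, rate)
                messages[node.index] = partials[node.index] @ P.T
        root = nodes[-1]
        per_cat_ll[ci] = np.log(np.maximum(partials[root.index] @ pi, 1e-300)) + logscale

        down: dict[int, np.ndarray] = {root.index: np.broadcast_to(pi, (ws.n_pat, n_states))}
        node_post: dict[str, np.ndarray] = {}
        for node in reversed(nodes):  # preorder
            if node.is_leaf:
                continue
            D = down[node.index]
            post = D * partials[node.index]
            norm = post.sum(axis=1, keepdims=True)
            node_post[node.label] = post / np.maximum(norm, 1e-300)
            for child in node.children:
                sib = np.ones((ws.n_pat, n_states))
                for other in node.children:
                    if other is not child:
                        sib = sib * messages[other.index]
                P = ws.transition(child, rate)
                Dc = (D * sib) @ P
                scale = Dc.max(axis=1, keepdims=True)
                down[child.index] = Dc / np.maximum(scale, 1e-300)
        per_cat_node_post.append(node_post)

    m = per_cat_ll.max(axis=0)
    resp = ws.rate_weights[:, None] * np.exp(per_cat_ll - m)
    resp /= resp.sum(axis=0, keepdims=True)  # (n_cat, n_pat)
    for label in cat_post:
        for ci in range(n_cat):
            cat_post[label] += resp[ci][:, None] * per_cat_node_post[ci][label]

    gap_frac = _descendant_gap_fraction(tree, msa.subset(tree.leaf_labels)) if \
        model.kind != "codon" else {n.label: np.zeros(ws.n_sites, bool) for n in internal}
    posterior = {lab: p[:, :][ws.site_to_pat] for lab, p in cat_post.items()}
    return AncestralProfile(
        states=model.states,
        node_labels=[n.label for n in internal],
        n_sites=ws.n_sites,
        posterior=posterior,
        gap_flag={lab: np.asarray(gap_frac[lab]) for lab in posterior},
    )


def joint_asr(tree: PhyloTree, msa: SequenceSet, model: SubstModel,
              tokenizer=None) -> dict[str, str]:
    """Joint reconstruction: the single most probable assignment of states to
    all internal nodes, per site.  Returns node label -> sequence.

    Gap-flagged node-sites (majority of descendant leaves gapped) are emitted
    as ``-``.
    """
    _require_rooted_labeled(tree)
    ws = _PruningWorkspace(tree, msa, model, tokenizer)
    nodes = ws.nodes
    root = nodes[-1]
    n_states = model.n_states
    log_pi = np.log(ws.model.frequencies)

    best_score = np.full(ws.n_pat, -np.inf)
    best_states: dict[int, np.ndarray] = {}

    for rate, weight in zip(ws.rates, ws.rate_weights):
        # C[node] (n_pat, n_parent_states); B[node] backpointers
        C: dict[int, np.ndarray] = {}
        B: dict[int, np.ndarray] = {}
        for node in nodes:
            if node is root:
                continue
            logP = np.log(np.maximum(ws.transition(node, rate), 1e-300))
            if node.is_leaf:
                obs = ws.patterns[ws.leaf_row[node.label]]
                c = np.zeros((ws.n_pat, n_states))
                known = obs >= 0
                c[known] = logP[:, obs[known]].T
                C[node.index] = c  # missing leaves contribute log(sum P) = 0
                B[node.index] = np.broadcast_to(
                    np.where(known, obs, 0)[:, None], (ws.n_pat, n_states))
            else:
                S = np.zeros((ws.n_pat, n_states))
                for child in node.children:
                    S += C[child.index]
                tmp = S[:, None, :] + logP[None, :, :]  # (pat, parent, state)
                C[node.index] = tmp.max(axis=2)
                B[node.index] = tmp.argmax(axis=2)
        S_root = np.zeros((ws.n_pat, n_states)) + log_pi[None, :]
        for child in root.children:
            S_root += C[child.index]
        score = S_root.max(axis=1) + np.log(weight)
        root_state = S_root.argmax(axis=1)

        # backtrack for this category
        states: dict[int, np.ndarray] = {root.index: root_state}
        for node in reversed(nodes):
            if node is root:
                continue
            parent_states = states[node.parent.index]
            states[node.index] = B[node.index][np.arange(ws.n_pat), parent_states]
        improved = score > best_score
        if improved.any():
            for idx, st in states.items():
                if idx not in best_states:
                    best_states[idx] = st.copy()
                else:
                    best_states[idx][improved] = st[improved]
            best_score = np.maximum(best_score, score)

    gap_frac = _descendant_gap_fraction(tree, msa.subset(tree.leaf_labels)) if \
        model.kind != "codon" else None
    out: dict[str, str] = {}
    join = "".join
    for node in nodes:
        if node.is_leaf:
            continue
        site_states = best_states[node.index][ws.site_to_pat]
        if isinstance(model.states, str):
            chars = [model.states[int(k)] for k in site_states]
        else:
            chars = [model.states[int(k)] for k in site_states]
        if gap_frac is not None:
            gaps = gap_frac[node.label]
            chars = ["-" if g else c for g, c in zip(gaps, chars)]
        out[node.label] = join(chars)
    return out


# ---------------------------------------------------------------------------
# Key-residue matrix extraction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KeyResidueMatrix:
    """Residues (and, for ancestors, posteriors) at selected BW positions.

    ``residues`` holds primary calls; tied predictions (top-two posteriors
    within ``tie_delta``) appear as ``"T/A"``.  ``posteriors`` holds the
    primary-call posterior probability (NaN for extant sequences).
    """

    residues: pd.DataFrame      # rows = sequence/node ids, cols = BW labels
    posteriors: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        """Cells like ``R(0.97)`` for ancestors, plain ``R`` otherwise."""
        out = self.residues.copy()
        for row in out.index:
            for col in out.columns:
                p = self.posteriors.loc[row, col]
                if not np.isnan(p):
                    out.loc[row, col] = f"{out.loc[row, col]}({p:.2f})"
        return out

    def to_tsv(self, path) -> None:
        # mirror the published layout: rows = BW labels, columns = taxa/nodes
        self.formatted().T.to_csv(path, sep="\t", index_label="bw_label")


def extract_key_residues(
    source: SequenceSet | AncestralProfile,
    bwmap: BWMap,
    labels: Sequence[str],
    tie_delta: float = DEFAULT_TIE_DELTA,
) -> KeyResidueMatrix:
    """Pull the residues at the given BW positions from extant sequences or
    from a marginal reconstruction.

    For ancestral profiles the MAP residue and its posterior are reported;
    when the top two posteriors differ by less than ``tie_delta`` both
    residues are listed (``"T/A"``).
    """
    cols = {lab: bwmap.column(lab) for lab in labels}
    if isinstance(source, SequenceSet):
        rows = {}
        for rid, seq in source.records:
            rows[rid] = {lab: seq[col] for lab, col in cols.items()}
        residues = pd.DataFrame.from_dict(rows, orient="index")[list(labels)]
        posteriors = pd.DataFrame(np.nan, index=residues.index, columns=list(labels))
        return KeyResidueMatrix(residues=residues, posteriors=posteriors)

    rows, prows = {}, {}
    for node in source.node_labels:
        r, p = {}, {}
        for lab, col in cols.items():
            if source.gap_flag[node][col]:
                r[lab], p[lab] = "-", np.nan
                continue
            res1, p1 = source.map_state(node, col)
            res2, p2 = source.second_state(node, col)
            if p1 - p2 < tie_delta:
                r[lab] = f"{res1}/{res2}"
            else:
                r[lab] = res1
            p[lab] = p1
        rows[node], prows[node] = r, p
    residues = pd.DataFrame.from_dict(rows, orient="index")[list(labels)]
    posteriors = pd.DataFrame.from_dict(prows, orient="index")[list(labels)]
    return KeyResidueMatrix(residues=residues, posteriors=posteriors)
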