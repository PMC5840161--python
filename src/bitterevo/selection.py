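"""Per-site dN/dS estimation from codon alignments by substitution counting.

The approach is a counting (SLAC-style) estimator.  Expected numbers of
synonymous and nonsynonymous *sites* per codon follow the Nei-Gojobori
(1986) fractional enumeration of one-step changes; changes that would create
a stop codon are not counted on either side.  Observed synonymous and
nonsynonymous *substitutions* are summed over all branches between
reconstructed (joint ancestral) codon states; multi-nucleotide codon changes
are averaged over all minimal stop-free mutational paths.  Each site's
omega = (Nd/N)/(Sd/S) is tested against neutrality with a two-sided binomial
test of the nonsynonymous fraction, giving positive / neutral / purifying
calls at a chosen significance level.

Codon evolution is modeled Muse-Gaut style (MG94): single-nucleotide codon
exchanges at a kappa-adjusted nucleotide rate, multiplied by omega when the
change is nonsynonymous.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.stats import binomtest

from .formats import BWMap, SequenceSet
from .phylo import PhyloTree, SubstModel

NUCLEOTIDES = "TCAG"
_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_table.stop_codons)
SENSE_CODONS: list[str] = sorted(
    c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
TRANSLATE = dict(_table.forward_table)


def is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def codon_tokenizer(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError(f"codon sequence length {len(seq)} not divisible by 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


# ---------------------------------------------------------------------------
# NG86 site counting
# ---------------------------------------------------------------------------

def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of a sense codon.

    Each of the nine one-step nucleotide changes contributes 1/3 of a site
    to the synonymous or nonsynonymous pool; changes producing a stop codon
    are counted on neither side.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    if codon not in CODON_INDEX:
        raise ValueError(f"not an unambiguous sense codon: {codon!r}")
    aa = TRANSLATE[codon]
    s = n = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            if TRANSLATE[alt] == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


def _count_path(path: Sequence[str]) -> tuple[float, float]:
    s = n = 0.0
    for a, b in zip(path, path[1:]):
        if TRANSLATE[a] == TRANSLATE[b]:
            s += 1.0
        else:
            n += 1.0
    return s, n


def count_codon_changes(a: str, b: str) -> tuple[float, float]:
    """Observed (synonymous, nonsynonymous) substitutions from codon ``a`` to
    ``b``, averaged over all minimal stop-free mutational paths."""
    a, b = a.upper(), b.upper()
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths: list[list[str]] = []
    for order in itertools.permutations(diff):
        path = [a]
        cur = a
        for pos in order:
            cur = cur[:pos] + b[pos] + cur[pos + 1:]
            path.append(cur)
        if any(c in STOP_CODONS for c in path[1:-1]):
            continue
        if a in STOP_CODONS or b in STOP_CODONS:
            continue
        paths.append(path)
    if not paths:  # endpoints valid but every route passes a stop: fall back
        paths = []
        for order in itertools.permutations(diff):
            path = [a]
            cur = a
            for pos in order:
                cur = cur[:pos] + b[pos] + cur[pos + 1:]
                path.append(cur)
            paths.append(path)
        paths = [p for p in paths if all(c not in STOP_CODONS for c in (p[0], p[-1]))]
    s = n = 0.0
    for p in paths:
        ps, pn = _count_path(p)
        s += ps
        n += pn
    k = len(paths)
    return s / k, n / k


# ---------------------------------------------------------------------------
# MG94 codon model
# ---------------------------------------------------------------------------

def codon_frequencies(nt_freqs: Sequence[float] | None = None) -> np.ndarray:
    """F1x4 codon frequencies (product of nucleotide frequencies over sense
    codons, renormalized).  ``nt_freqs`` is in ACGT order; default uniform."""
    f = np.full(4, 0.25) if nt_freqs is None else np.asarray(nt_freqs, float)
    f = f / f.sum()
    nt_idx = {n: i for i, n in enumerate("ACGT")}
    pi = np.array([f[nt_idx[c[0]]] * f[nt_idx[c[1]]] * f[nt_idx[c[2]]]
                   for c in SENSE_CODONS])
    return pi / pi.sum()


def mg94_neighbors() -> list[list[tuple[int, int, bool, bool]]]:
    """For each sense codon: list of (target index, changed-position target
    nucleotide index in ACGT, is_transition, is_synonymous)."""
    nt_idx = {n: i for i, n in enumerate("ACGT")}
    out: list[list[tuple[int, int, bool, bool]]] = []
    for a in SENSE_CODONS:
        row: list[tuple[int, int, bool, bool]] = []
        for pos in range(3):
            for nt in "ACGT":
                if nt == a[pos]:
                    continue
                b = a[:pos] + nt + a[pos + 1:]
                if b in STOP_CODONS:
                    continue
                row.append((CODON_INDEX[b], nt_idx[nt], is_transition(a[pos], nt),
                            TRANSLATE[a] == TRANSLATE[b]))
        out.append(row)
    return out


_NEIGHBORS = mg94_neighbors()


def mg94_rate_matrix(kappa: float = 2.0, omega: float = 1.0,
                     nt_freqs: Sequence[float] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Unscaled MG94 generator and its stationary codon frequencies.

    ``q[a,b] = kappa^transition * pi_nt(target) * (omega if nonsynonymous)``
    for single-nucleotide changes between sense codons.
    """
    f = np.full(4, 0.25) if nt_freqs is None else np.asarray(nt_freqs, float)
    f = f / f.sum()
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    for ai, row in enumerate(_NEIGHBORS):
        for bi, nt, ti, syn in row:
            rate = f[nt] * (kappa if ti else 1.0)
            if not syn:
                rate *= omega
            Q[ai, bi] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, codon_frequencies(f)


def mg94_model(kappa: float = 2.0, omega: float = 1.0,
               nt_freqs: Sequence[float] | None = None) -> SubstModel:
    """MG94 as a reversible :class:`SubstModel` (rate-1 scaled), usable with
    the generic pruning/ASR machinery."""
    Q, pi = mg94_rate_matrix(kappa, omega, nt_freqs)
    S = Q / pi[None, :]
    np.fill_diagonal(S, 0.0)
    S = (S + S.T) / 2.0  # symmetric up to float noise by reversibility
    return SubstModel(kind="codon", exchangeability=S, frequencies=pi,
                      states=SENSE_CODONS)


def empirical_nt_freqs(codon_msa: SequenceSet) -> np.ndarray:
    # one pseudocount per nucleotide keeps frequencies strictly positive on
    # short alignments (a zero frequency would degenerate the codon model)
    counts = dict.fromkeys("ACGT", 1)
    for _, seq in codon_msa.records:
        for ch in seq:
            if ch in counts:
                counts[ch] += 1
    total = sum(counts.values())
    return np.array([counts[n] / total for n in "ACGT"])


# ---------------------------------------------------------------------------
# Per-site dN/dS
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SiteSelectionTable:
    """Per-codon-site selection summary; ``table`` columns: site (1-based),
    N_sites, S_sites, Nd, Sd, omega, p_value, class."""

    table: pd.DataFrame
    alpha: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def with_bw_labels(self, bwmap: BWMap) -> pd.DataFrame:
        """Join BW labels onto codon sites (site i <-> protein MSA column
        i-1 of the alignment the map was built on)."""
        col_to_label = bwmap.column_to_label
        out = self.table.copy()
        out.insert(1, "bw_label", [col_to_label.get(s - 1, "") for s in out["site"]])
        return out


def site_dnds(
    codon_msa: SequenceSet,
    tree: PhyloTree,
    ancestors: dict[str, str] | None = None,
    kappa: float = 2.0,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> SiteSelectionTable:
    """Count-based per-site dN/dS over a codon alignment on a rooted tree.

    If ``ancestors`` (node label -> codon sequence) is not supplied, internal
    states are reconstructed by joint ancestral reconstruction under a
    neutral (omega=1) MG94 model with empirical nucleotide frequencies.
    Sites with no inferred changes are classed neutral with undefined omega.
    """
    from .ancestral import joint_asr

    n_sites = len(codon_msa.records[0][1])
    if n_sites % 3:
        raise ValueError("codon alignment length must be divisible by 3")
    n_codons = n_sites // 3

    if ancestors is None:
        model = mg94_model(kappa=kappa, omega=1.0,
                           nt_freqs=empirical_nt_freqs(codon_msa))
        ancestors = joint_asr(tree, codon_msa, model, tokenizer=codon_tokenizer)

    seqs: dict[str, list[str]] = {}
    for rid, seq in codon_msa.records:
        seqs[rid] = codon_tokenizer(seq)
    for label, seq in ancestors.items():
        seqs[label] = codon_tokenizer(seq) if isinstance(seq, str) else list(seq)

    Nd = np.zeros(n_codons)
    Sd = np.zeros(n_codons)
    undefined = np.zeros(n_codons, dtype=bool)

    branches = [(n.parent.label, n.label) for n in tree.postorder() if n.parent is not None]
    for parent_label, child_label in branches:
        pa, ch = seqs.get(parent_label), seqs.get(child_label)
        if pa is None or ch is None:
            raise KeyError(f"no sequence for node {parent_label!r} or {child_label!r}")
        for k in range(n_codons):
            ca, cb = pa[k], ch[k]
            if ca in STOP_CODONS or cb in STOP_CODONS:
                undefined[k] = True
                continue
            if ca not in CODON_INDEX or cb not in CODON_INDEX:
                continue  # gapped or ambiguous codon: missing data

            s, n = count_codon_changes(ca, cb)
            Sd[k] += s
            Nd[k] += n

    # expected site counts: average NG86 over every codon observed or
    # reconstructed at the site
    N_sites = np.zeros(n_codons)
    S_sites = np.zeros(n_codons)
    for k in range(n_codons):
        vals = [seq[k] for seq in seqs.values() if seq[k] in CODON_INDEX]
        if not vals:
            undefined[k] = True
            continue
        counts = [ng86_site_counts(c) for c in vals]
        S_sites[k] = float(np.mean([c[0] for c in counts]))
        N_sites[k] = float(np.mean([c[1] for c in counts]))

    rows = []
    pvals = []
    for k in range(n_codons):
        total_sites = N_sites[k] + S_sites[k]
        nd, sd = Nd[k], Sd[k]
        if undefined[k] or total_sites == 0:
            rows.append((k + 1, N_sites[k], S_sites[k], nd, sd, np.nan, np.nan, "undefined"))
            pvals.append(np.nan)
            continue
        if nd + sd == 0:
            rows.append((k + 1, N_sites[k], S_sites[k], nd, sd, np.nan, 1.0, "neutral"))
            pvals.append(1.0)
            continue
        if sd > 0 and S_sites[k] > 0:
            omega = (nd / N_sites[k]) / (sd / S_sites[k])
        elif nd > 0:
            omega = np.inf
        else:
            omega = np.nan
        p_neutral = N_sites[k] / total_sites
        n_obs = int(round(nd + sd))
        k_obs = min(int(round(nd)), n_obs)
        p = binomtest(k_obs, n_obs, p_neutral, alternative="two-sided").pvalue
        rows.append((k + 1, N_sites[k], S_sites[k], nd, sd, omega, p, None))
        pvals.append(p)

    table = pd.DataFrame(rows, columns=["site", "N_sites", "S_sites", "Nd", "Sd",
                                        "omega", "p_value", "class"])
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        mask = table["class"].isna()
        if mask.any():
            adj = multipletests(table.loc[mask, "p_value"], method="fdr_bh")[1]
            table.loc[mask, "p_value"] = adj

    def classify(row) -> str:
        if row["class"] is not None and isinstance(row["class"], str):
            return row["class"]
        if row["p_value"] < alpha and row["omega"] > 1:
            return "positive"
        if row["p_value"] < alpha and row["omega"] < 1:
            return "purifying"
        return "neutral"

    table["class"] = table.apply(classify, axis=1)
    return SiteSelectionTable(table=table, alpha=alpha)
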