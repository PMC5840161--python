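"""Sequence and alignment handling: FASTA I/O, Ballesteros-Weinstein column
mapping, and identity/length filtering of candidate homologs.

The Ballesteros-Weinstein (BW) scheme indexes GPCR residues as X.50 +/- offset
within transmembrane helix X, so that equivalent pocket positions can be
compared across receptors.  Here a BW map anchors those labels onto multiple
sequence alignment (MSA) columns through a chosen reference sequence: the
annotation gives 1-based positions in the *ungapped* reference, and each
annotated residue's MSA column inherits the label.  Loop residues (e.g. the
second extracellular loop) carry plain string labels such as ``ECL2`` in the
same map.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY-X")
DNA_ALPHABET = set("ACGT-N")

# Fixed pairwise-alignment scheme used for identity filtering (EMBOSS
# needle-style defaults: BLOSUM62, gap open 10, gap extend 0.5).
IDENTITY_ALIGN_SCHEME = {"matrix": "BLOSUM62", "open_gap_score": -10.0, "extend_gap_score": -0.5}


@dataclasses.dataclass
class SequenceSet:
    """An ordered collection of named sequences, optionally aligned.

    Parameters
    ----------
    records
        List of ``(id, sequence)`` pairs.  Ids must be unique; sequences are
        upper-cased on construction.
    aligned
        If true, all sequences must have equal length.
    alphabet
        ``"protein"`` (20 amino acids plus ``-`` and ``X``) or ``"dna"``.
    """

    records: list[tuple[str, str]]
    aligned: bool = False
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        self.records = [(rid, seq.upper()) for rid, seq in self.records]
        seen: set[str] = set()
        for rid, _ in self.records:
            if rid in seen:
                raise ValueError(f"duplicate sequence id: {rid!r}")
            seen.add(rid)
        if self.aligned and self.records:
            lengths = {len(s) for _, s in self.records}
            if len(lengths) > 1:
                raise ValueError(f"aligned set has unequal lengths: {sorted(lengths)}")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        for rid, seq in self.records:
            bad = set(seq) - allowed
            if bad:
                raise ValueError(f"sequence {rid!r} contains invalid characters {sorted(bad)}")

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def n_columns(self) -> int:
        if not self.aligned:
            raise ValueError("n_columns is defined only for aligned sets")
        return len(self.records[0][1]) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rid: str) -> bool:
        return any(r == rid for r, _ in self.records)

    def get(self, rid: str) -> str:
        for r, seq in self.records:
            if r == rid:
                return seq
        raise KeyError(rid)

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        wanted = list(ids)
        missing = [i for i in wanted if i not in self]
        if missing:
            raise KeyError(f"ids not in set: {missing}")
        order = {rid: k for k, (rid, _) in enumerate(self.records)}
        wanted.sort(key=order.__getitem__)
        return SequenceSet(
            [(rid, self.get(rid)) for rid in wanted], aligned=self.aligned, alphabet=self.alphabet
        )


def ungapped_length(seq: str) -> int:
    return len(seq) - seq.count("-")


def read_fasta(path: str | Path, aligned: bool | None = None, alphabet: str = "protein") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    ``aligned=None`` auto-detects: the set is marked aligned when it contains
    gaps or when all sequences share one length and there are at least two.
    """
    path = Path(path)
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if aligned is None:
        lengths = {len(s) for _, s in records}
        has_gap = any("-" in s for _, s in records)
        aligned = has_gap or (len(lengths) == 1 and len(records) > 1)
    return SequenceSet(records, aligned=aligned, alphabet=alphabet)


def write_fasta(seqset: SequenceSet, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in seqset.records]
    SeqIO.write(recs, str(path), "fasta")


@dataclasses.dataclass
class BWMap:
    """Bijective map between MSA columns (0-based) and BW/loop labels."""

    reference_id: str
    column_to_label: dict[int, str]
    label_to_column: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label_to_column:
            self.label_to_column = {lab: col for col, lab in self.column_to_label.items()}
        if len(self.label_to_column) != len(self.column_to_label):
            raise ValueError("BW labels are not unique across columns")

    def column(self, label: str) -> int:
        if label not in self.label_to_column:
            raise KeyError(f"BW label {label!r} is not mapped to any MSA column")
        return self.label_to_column[label]

    @property
    def labels(self) -> list[str]:
        return list(self.label_to_column)


def map_bw_numbers(
    msa: SequenceSet,
    reference_id: str,
    annotation: Sequence[tuple[int, str]],
) -> BWMap:
    """Anchor BW labels onto MSA columns through an annotated reference.

    ``annotation`` pairs 1-based positions in the ungapped reference sequence
    with BW (or loop) labels.  The MSA column holding each annotated reference
    residue receives the label; all other columns remain unmapped.
    """
    if not msa.aligned:
        raise ValueError("BW mapping requires an aligned sequence set")
    refseq = msa.get(reference_id)
    # ungapped position (1-based) -> MSA column (0-based)
    pos_to_col: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(refseq):
        if ch != "-":
            pos += 1
            pos_to_col[pos] = col
    nres = pos
    column_to_label: dict[int, str] = {}
    for ref_pos, label in annotation:
        if not 1 <= ref_pos <= nres:
            raise ValueError(
                f"annotation position {ref_pos} outside ungapped reference "
                f"length {nres} ({reference_id})"
            )
        column_to_label[pos_to_col[ref_pos]] = label
    return BWMap(reference_id=reference_id, column_to_label=column_to_label)


def read_bw_annotation(path: str | Path) -> list[tuple[int, str]]:
    """Read a TSV of ``ref_position<TAB>bw_label`` rows (1-based positions)."""
    out: list[tuple[int, str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos_s, label = line.split("\t")[:2]
        out.append((int(pos_s), label))
    return out


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global alignment under the fixed scheme.

    Identity = matches / aligned columns, where columns gapped in both
    sequences do not arise in a pairwise alignment; gap columns count in the
    denominator (BLAST-style).
    """
    a = seq_a.replace("-", "")
    b = seq_b.replace("-", "")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(IDENTITY_ALIGN_SCHEME["matrix"])
    aligner.open_gap_score = IDENTITY_ALIGN_SCHEME["open_gap_score"]
    aligner.extend_gap_score = IDENTITY_ALIGN_SCHEME["extend_gap_score"]
    aln = aligner.align(a.replace("X", "A"), b.replace("X", "A"))[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    ncols = len(s1)
    return 100.0 * matches / ncols


def filter_homologs(
    seqs: SequenceSet,
    query_id: str,
    min_identity_pct: float = 55.0,
    min_length: int = 265,
) -> SequenceSet:
    """Keep sequences with identity >= threshold to the query and ungapped
    length strictly greater than ``min_length``; the query is always retained.

    Mirrors the homolog-screening rule used for bitter-taste-receptor
    reference sets: candidates below 55% identity or of 265 residues or fewer
    (fragments) are discarded.
    """
    if query_id not in seqs:
        raise KeyError(f"query id {query_id!r} not present in sequence set")
    query = seqs.get(query_id)
    keep: list[str] = []
    for rid, seq in seqs.records:
        if rid == query_id:
            keep.append(rid)
            continue
        if ungapped_length(seq) <= min_length:
            continue
        if pairwise_identity(query, seq) >= min_identity_pct:
            keep.append(rid)
    return seqs.subset(keep)
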