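"""End-to-end orchestration: filter -> tree -> ASR -> relative times ->
selection -> binder calls, from one configuration.

The pipeline consumes an aligned protein FASTA (plus, optionally, a matching
codon alignment and a user-supplied Newick tree), applies the homolog
filter, builds or reads the phylogeny, roots it on the outgroup, labels
internal nodes deterministically (postorder, ``N#``), reconstructs
ancestors, estimates relative divergence times, classifies every extant and
ancestral sequence for strychnine binding, and (when codon data are given)
computes per-site dN/dS.  All outputs are plain TSV/FASTA/Newick; a JSON run
log records versions, the seed, and a hash of the configuration.

A stage failure aborts the run with the stage name; outputs already written
are renamed with a ``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .ancestral import extract_key_residues, marginal_asr
from .binding import classify_binder, load_catalog
from .chronos import relative_rates
from .formats import (SequenceSet, filter_homologs, map_bw_numbers,
                      read_bw_annotation, read_fasta, write_fasta)
from .phylo import (PhyloTree, distance_matrix, load_empirical_model,
                    nj_tree, optimize_branch_lengths, poisson_model)
from .selection import site_dnds


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    protein_fasta: str
    bw_annotation: str
    query_id: str
    outgroup_ids: list[str]
    codon_fasta: str | None = None
    newick: str | None = None
    catalog: str | None = None           # bundled catalog when None
    min_identity_pct: float = 55.0
    min_length: int = 265
    alpha: float = 0.05
    tie_delta: float = 0.05
    model: str = "JTT"                   # JTT | poisson
    gamma_shape: float | None = None
    n_rate_categories: int = 1
    optimize_branches: bool = True
    kappa: float = 2.0
    seed: int = 0
    outdir: str = "bitterevo_out"

    def validate(self) -> None:
        for attr in ("protein_fasta", "bw_annotation"):
            p = getattr(self, attr)
            if not Path(p).is_file():
                raise FileNotFoundError(f"{attr}: no such file: {p}")
        for attr in ("codon_fasta", "newick", "catalog"):
            p = getattr(self, attr)
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"{attr}: no such file: {p}")
        if not 0 <= self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be in [0, 100]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages; returns a map of output names to file paths."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    log: dict[str, Any] = {
        "package": "bitterevo",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "inputs": {"protein_fasta": _file_hash(config.protein_fasta)},
        "stages": [],
    }
    stage_name = "setup"

    def record(name: str, t0: float) -> None:
        log["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3)})

    try:
        # (a) filter -------------------------------------------------------
        stage_name = "filter"
        t0 = time.time()
        msa = read_fasta(config.protein_fasta, aligned=True)
        filtered = filter_homologs(msa, config.query_id,
                                   config.min_identity_pct, config.min_length)
        kept_og = [o for o in config.outgroup_ids if o in msa]
        for og in kept_og:  # outgroup is for rooting, exempt from the filter
            if og not in filtered:
                filtered = msa.subset(filtered.ids + [og])
        path = outdir / "filtered.fasta"
        write_fasta(filtered, path)
        outputs["filtered"] = path
        record(stage_name, t0)

        # model ------------------------------------------------------------
        stage_name = "model"
        t0 = time.time()
        if config.model.lower() == "poisson":
            model = poisson_model(gamma_shape=config.gamma_shape,
                                  n_rate_categories=config.n_rate_categories)
        else:
            model = load_empirical_model(config.model,
                                         gamma_shape=config.gamma_shape,
                                         n_rate_categories=config.n_rate_categories)
        record(stage_name, t0)

        # (b) tree ---------------------------------------------------------
        stage_name = "tree"
        t0 = time.time()
        if config.newick:
            tree = PhyloTree.read(config.newick)
        else:
            D, ids = distance_matrix(filtered, model)
            tree = nj_tree(D, ids)
            if config.optimize_branches:
                tree = optimize_branch_lengths(tree, filtered, model)
        rooted = tree.root_with_outgroup(config.outgroup_ids) \
            if config.outgroup_ids else tree
        if not rooted.rooted:
            raise ValueError("tree is unrooted and no outgroup was given")
        rooted.label_internal_nodes()
        path = outdir / "tree.nwk"
        rooted.write(path)
        outputs["tree"] = path
        record(stage_name, t0)

        # (c) ASR + key-residue matrix --------------------------------------
        stage_name = "asr"
        t0 = time.time()
        profile = marginal_asr(rooted, filtered, model)
        annotation = read_bw_annotation(config.bw_annotation)
        bwmap = map_bw_numbers(filtered, config.query_id, annotation)
        catalog = load_catalog(config.catalog)
        labels = catalog.labels
        og_clade = _outgroup_clade_labels(rooted, config.outgroup_ids)
        extant = extract_key_residues(filtered, bwmap, labels,
                                      tie_delta=config.tie_delta)
        anc = extract_key_residues(profile, bwmap, labels,
                                   tie_delta=config.tie_delta)
        anc.residues = anc.residues.drop(index=[l for l in og_clade
                                                if l in anc.residues.index])
        anc.posteriors = anc.posteriors.loc[anc.residues.index]
        matrix = pd.concat([extant.formatted(), anc.formatted()])
        path = outdir / "key_residues.tsv"
        matrix.T.to_csv(path, sep="\t", index_label="bw_label")
        outputs["key_residues"] = path
        record(stage_name, t0)

        # (d) binder calls --------------------------------------------------
        stage_name = "classify"
        t0 = time.time()
        rows = []
        residue_tables = [extant.residues, anc.residues]
        for table in residue_tables:
            for rid in table.index:
                if rid in config.outgroup_ids:
                    continue
                res = table.loc[rid].to_dict()
                call = classify_binder(res, catalog)
                rows.append({
                    "name": rid,
                    "verdict": call.verdict,
                    "verdict_R10": call.mode_verdicts["R10"],
                    "verdict_R46": call.mode_verdicts["R46"],
                    "evidence": ";".join(
                        f"{e['mode']}:{e['bw_label']}:{e['key']}>{e['observed']}={e['effect']}"
                        for e in call.evidence),
                })
        path = outdir / "binder_calls.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        outputs["binder_calls"] = path
        record(stage_name, t0)

        # (e) relative times ------------------------------------------------
        stage_name = "reltime"
        t0 = time.time()
        reltime = relative_rates(rooted, config.outgroup_ids)
        path = outdir / "reltime.tsv"
        reltime.to_tsv(path)
        outputs["reltime"] = path
        record(stage_name, t0)

        # (f) selection -----------------------------------------------------
        if config.codon_fasta:
            stage_name = "dnds"
            t0 = time.time()
            codon_msa = read_fasta(config.codon_fasta, aligned=True, alphabet="dna")
            codon_tree = rooted.copy()
            keep = set(codon_msa.ids)
            table = site_dnds(codon_msa, _prune_to(codon_tree, keep),
                              kappa=config.kappa, alpha=config.alpha)
            joined = table.with_bw_labels(bwmap)
            path = outdir / "selection.tsv"
            joined.to_csv(path, sep="\t", index=False, float_format="%.6g")
            outputs["selection"] = path
            record(stage_name, t0)

        # (g) run log -------------------------------------------------------
        stage_name = "log"
        path = outdir / "run_log.json"
        path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
        outputs["run_log"] = path
        return outputs

    except Exception as exc:  # noqa: BLE001 - report the failing stage
        for name, p in outputs.items():
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise PipelineError(stage_name, exc) from exc


def _outgroup_clade_labels(rooted: PhyloTree, outgroup_ids: Sequence[str]) -> set[str]:
    """Internal-node labels inside the outgroup clade (excluded from
    ancestral reporting)."""
    if not outgroup_ids:
        return set()
    og = set(outgroup_ids)
    out: set[str] = set()
    for child in rooted.root.children:
        leaves = {n.label for n in child_subtree_leaves(child)}
        if leaves <= og:
            stack = [child]
            while stack:
                n = stack.pop()
                if not n.is_leaf and n.label:
                    out.add(n.label)
                stack.extend(n.children)
    return out


def child_subtree_leaves(node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def _prune_to(tree: PhyloTree, keep: set[str]) -> PhyloTree:
    """Restriction of the tree to a subset of leaves (summing branch lengths
    through removed degree-2 nodes)."""
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in tree.postorder():
            if node.is_leaf and node.label not in keep and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
                break
            if not node.is_leaf and not node.children and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
                break
            if len(node.children) == 1 and node.parent is not None:
                only = node.children[0]
                only.length = (only.length or 0.0) + (node.length or 0.0)
                only.parent = node.parent
                node.parent.children[node.parent.children.index(node)] = only
                changed = True
                break
        if changed:
            tree = PhyloTree(tree.root, rooted=tree.rooted)
    while len(tree.root.children) == 1:
        tree = PhyloTree(tree.root.children[0], rooted=None)
        tree.root.parent = None
        tree.root.length = None
    return tree
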