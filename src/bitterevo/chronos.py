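"""Relative divergence times and lineage rates from a rooted tree.

This implements a RelTime-style relative dating scheme.  The defining
constraint of that family of methods is that the two lineages descending
from any node span the *same* elapsed time, so differences in their summed
branch lengths must be absorbed by lineage-specific rates.  Concretely:

* ``L(v)`` is the tip-weighted mean path length from node ``v`` to its
  descendant tips (each child contributes ``b_c + L(c)`` weighted by its tip
  count).
* Sibling lineage rates are set proportional to their ``b_c + L(c)``,
  propagated multiplicatively from the ingroup root (rate 1), i.e.
  ``r(c) = r(v) * (b_c + L(c)) / L(v)``.
* Node times follow from rate-corrected heights, which telescope to
  ``T(v) = L(v) / r(v)``, normalized so the ingroup root has time 1 and tips
  time 0.

Times are relative (no calibration); rates are reported mean-normalized.
The outgroup is used only to locate the root and is excluded from rate and
time estimation.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .phylo import PhyloTree, TreeNode


@dataclasses.dataclass
class RelTimeResult:
    """Relative node times, per-branch lineage rates, and elapsed times.

    ``relative_time`` maps node label -> time (tips 0, ingroup root 1);
    ``relative_rate`` maps child-node label -> mean-normalized rate of the
    branch above it; ``elapsed`` maps child-node label -> time elapsed along
    that branch (parent time minus child time).
    """

    relative_time: dict[str, float]
    relative_rate: dict[str, float]
    elapsed: dict[str, float]
    ingroup_root: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, t in self.relative_time.items():
            rows.append({
                "node": label,
                "relative_time": t,
                "relative_rate": self.relative_rate.get(label, float("nan")),
                "elapsed": self.elapsed.get(label, float("nan")),
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Arbitrarily resolve multifurcations with zero-length branches."""
    tree = tree.copy()
    changed = False
    for node in list(tree.postorder()):
        while len(node.children) > 2:
            a = node.children.pop()
            b = node.children.pop()
            joint = TreeNode(label=None, length=0.0)
            joint.parent = node
            for x in (a, b):
                x.parent = joint
                joint.children.append(x)
            node.children.append(joint)
            changed = True
    if changed:
        return PhyloTree(tree.root, rooted=tree.rooted)
    return tree


def relative_rates(tree: PhyloTree, outgroup_ids: Sequence[str] = ()) -> RelTimeResult:
    """Estimate relative lineage rates and node divergence times.

    The tree must be rooted (or an outgroup must be given, in which case the
    tree is rooted on the outgroup edge first; a non-monophyletic outgroup
    triggers a warning and the root is placed on the outgroup MRCA edge).
    """
    if outgroup_ids:
        og = set(outgroup_ids)
        rooted = tree.root_with_outgroup(list(outgroup_ids))
        # check monophyly on the rooted tree
        for child in rooted.root.children:
            below = {n.label for n in _subtree_leaves(child)}
            if below == og:
                break
        else:
            warnings.warn("outgroup is not monophyletic; root placed on the "
                          "outgroup MRCA edge", stacklevel=2)
        tree = rooted
    elif not tree.rooted:
        raise ValueError("relative_rates requires a rooted tree or an outgroup")

    tree = _resolve_polytomies(tree)
    tree.label_internal_nodes()

    # locate the ingroup root: the root child whose subtree holds no outgroup
    og = set(outgroup_ids)
    if og:
        candidates = [c for c in tree.root.children
                      if not ({n.label for n in _subtree_leaves(c)} & og)]
        if len(candidates) != 1:
            raise ValueError("root does not cleanly separate outgroup from ingroup")
        ig_root = candidates[0]
    else:
        ig_root = tree.root

    # bottom-up: tip counts and tip-weighted mean path lengths
    L: dict[int, float] = {}
    ntips: dict[int, int] = {}
    order = [n for n in tree.postorder() if _in_subtree(n, ig_root)]
    for node in order:
        if node.is_leaf:
            L[node.index], ntips[node.index] = 0.0, 1
        else:
            tot = sum(ntips[c.index] for c in node.children)
            L[node.index] = sum(
                ntips[c.index] * ((c.length or 0.0) + L[c.index]) for c in node.children
            ) / tot
            ntips[node.index] = tot

    # top-down lineage rates
    rate: dict[int, float] = {ig_root.index: 1.0}
    for node in reversed(order):  # preorder within ingroup
        if node.is_leaf:
            continue
        Lv = L[node.index]
        for c in node.children:
            path = (c.length or 0.0) + L[c.index]
            if path <= 0.0:
                # unidentifiable (0/0): rate 1 for terminal branches by
                # convention, parent's rate for internal zero-length branches
                rate[c.index] = 1.0 if c.is_leaf else rate[node.index]
            elif Lv <= 0.0:
                rate[c.index] = rate[node.index]
            else:
                rate[c.index] = rate[node.index] * path / Lv

    scale = L[ig_root.index]
    if scale <= 0:
        raise ValueError("ingroup has zero total depth; cannot compute times")

    relative_time: dict[str, float] = {}
    for node in order:
        t = (L[node.index] / rate[node.index]) / scale if rate[node.index] > 0 else 0.0
        relative_time[node.label] = t

    branch_nodes = [n for n in order if n is not ig_root]
    raw = {n.label: rate[n.index] for n in branch_nodes}
    mean_rate = sum(raw.values()) / len(raw) if raw else 1.0
    relative_rate = {lab: r / mean_rate for lab, r in raw.items()}

    elapsed: dict[str, float] = {}
    for n in branch_nodes:
        elapsed[n.label] = relative_time[n.parent.label] - relative_time[n.label]

    return RelTimeResult(
        relative_time=relative_time,
        relative_rate=relative_rate,
        elapsed=elapsed,
        ingroup_root=ig_root.label,
    )


def _subtree_leaves(node: TreeNode):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def _in_subtree(node: TreeNode, ancestor: TreeNode) -> bool:
    x = node
    while x is not None:
        if x is ancestor:
            return True
        x = x.parent
    return False


def annotated_newick(tree: PhyloTree, result: RelTimeResult) -> str:
    """Newick with relative times as node comments (``[&time=...]``)."""
    def fmt(node: TreeNode) -> str:
        if node.children:
            inner = ",".join(fmt(c) for c in node.children)
            s = f"({inner})"
        else:
            s = ""
        if node.label:
            s += node.label
            t = result.relative_time.get(node.label)
            if t is not None:
                s += f"[&time={t:.6g}]"
        if node.length is not None:
            s += f":{node.length:.12g}"
        return s
    return fmt(tree.root) + ";"
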