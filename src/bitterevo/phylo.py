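"""Trees, substitution models, pruning likelihood, distances, neighbor
joining, and maximum-likelihood branch lengths.

The likelihood machinery is alphabet-agnostic (it works for the 20 amino
acids as well as for the 61 sense codons) and follows the standard
time-reversible continuous-time Markov chain construction: an exchangeability
matrix ``S`` and equilibrium frequencies ``pi`` define ``Q = S diag(pi)``,
rescaled to one expected substitution per site per unit branch length.
Transition matrices come from the eigendecomposition of the symmetrized
generator.  Site likelihoods are computed by Felsenstein's pruning algorithm
with per-node rescaling, and among-site rate variation uses the
equal-probability discrete gamma approximation.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import io
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc

from .formats import SequenceSet

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"  # PAML order, matches bundled .dat files


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeNode:
    __slots__ = ("label", "length", "parent", "children", "index")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length  # branch above this node, substitutions/site
        self.parent: "TreeNode | None" = None
        self.children: list["TreeNode"] = []
        self.index: int = -1

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted or unrooted phylogeny with branch lengths.

    Unrooted trees are stored with a basal multifurcation; ``rooted`` is true
    when the root has exactly two children (or when explicitly flagged).
    """

    def __init__(self, root: TreeNode, rooted: bool | None = None):
        self.root = root
        self.rooted = (len(root.children) == 2) if rooted is None else rooted
        self._index()

    # -- construction / IO ---------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        root = _from_dendropy(dtree.seed_node)
        for node in _iter_nodes(root):
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length {node.length} on node {node.label!r}")
        return cls(root, rooted=rooted)

    @classmethod
    def read(cls, path: str | Path, rooted: bool | None = None) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text(), rooted=rooted)

    def to_newick(self) -> str:
        buf = io.StringIO()
        _write_newick(self.root, buf)
        buf.write(";")
        return buf.getvalue()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- traversal / indexing ------------------------------------------------

    def _index(self) -> None:
        """Assign postorder indices: leaves and internals interleaved, root last."""
        self._postorder: list[TreeNode] = list(_postorder(self.root))
        for i, node in enumerate(self._postorder):
            node.index = i

    def postorder(self) -> list[TreeNode]:
        return self._postorder

    def preorder(self) -> list[TreeNode]:
        return list(reversed(self._postorder))

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self._postorder if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    @property
    def n_nodes(self) -> int:
        return len(self._postorder)

    def find(self, label: str) -> TreeNode:
        for n in self._postorder:
            if n.label == label:
                return n
        raise KeyError(f"no node labeled {label!r}")

    def copy(self) -> "PhyloTree":
        return PhyloTree(_copy_subtree(self.root), rooted=self.rooted)

    def label_internal_nodes(self, prefix: str = "N", start: int = 1) -> None:
        """Deterministically label unlabeled internal nodes by postorder number."""
        k = start
        for node in self._postorder:
            if not node.is_leaf:
                if not node.label:
                    node.label = f"{prefix}{k}"
                k += 1

    def mrca(self, labels: Iterable[str]) -> TreeNode:
        targets = set(labels)
        found: dict[TreeNode, set[str]] = {}
        for node in self._postorder:
            if node.is_leaf:
                found[node] = {node.label} & targets
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= found[c]
                found[node] = acc
            if found[node] == targets:
                return node
        raise KeyError(f"labels not all present: {sorted(targets)}")

    # -- rooting -------------------------------------------------------------

    def root_with_outgroup(self, outgroup_ids: Sequence[str]) -> "PhyloTree":
        """Return a rooted copy with the root on the branch separating the
        outgroup from the rest, splitting that branch at its midpoint."""
        tree = self.copy()
        leaf_set = set(tree.leaf_labels)
        missing = [o for o in outgroup_ids if o not in leaf_set]
        if missing:
            raise KeyError(f"outgroup taxa not in tree: {missing}")
        ingroup = leaf_set - set(outgroup_ids)
        node = tree.mrca(outgroup_ids)
        if node is tree.root:
            # outgroup not monophyletic as drawn; root on the ingroup MRCA edge
            node = tree.mrca(ingroup)
            if node is tree.root:
                raise ValueError("cannot place root: outgroup and ingroup both span the tree")
        rerooted = _reroot_on_edge(node)
        return PhyloTree(rerooted, rooted=True)


def _from_dendropy(dnode) -> TreeNode:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = TreeNode(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def _iter_nodes(root: TreeNode) -> Iterator[TreeNode]:
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _postorder(root: TreeNode) -> Iterator[TreeNode]:
    stack: list[tuple[TreeNode, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            yield node
        else:
            stack.append((node, True))
            for child in reversed(node.children):
                stack.append((child, False))


def _write_newick(node: TreeNode, buf: io.StringIO) -> None:
    if node.children:
        buf.write("(")
        for i, child in enumerate(node.children):
            if i:
                buf.write(",")
            _write_newick(child, buf)
        buf.write(")")
    if node.label:
        buf.write(_quote_label(node.label))
    if node.length is not None:
        buf.write(f":{node.length:.12g}")


def _quote_label(label: str) -> str:
    if any(c in label for c in " (),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _copy_subtree(node: TreeNode) -> TreeNode:
    new = TreeNode(label=node.label, length=node.length)
    for child in node.children:
        new.add_child(_copy_subtree(child))
    return new


def _reroot_on_edge(node: TreeNode) -> TreeNode:
    """Re-hang the tree so the root sits at the midpoint of the branch above
    ``node``.  ``node`` keeps its subtree; the rest of the tree is inverted."""
    old_parent = node.parent
    if old_parent is None:
        raise ValueError("node is already the root")
    half = (node.length or 0.0) / 2.0
    old_parent.children.remove(node)
    node.parent = None
    inverted = _invert_upward(old_parent)
    new_root = TreeNode(label=None, length=None)
    node.length = half
    new_root.add_child(node)
    inverted.length = half
    new_root.add_child(inverted)
    # collapse a degree-2 node left where the old root used to be
    _suppress_unifurcations(new_root)
    return new_root


def _invert_upward(start: TreeNode) -> TreeNode:
    """Invert the ancestor path of ``start`` so each former parent becomes a
    child, carrying the branch length of the edge that joined them."""
    path: list[TreeNode] = []
    x: TreeNode | None = start
    while x is not None:
        path.append(x)
        x = x.parent
    lengths = [p.length for p in path]  # lengths[i] = edge path[i] -- path[i+1]
    for i in range(len(path) - 1):
        path[i + 1].children.remove(path[i])
    for i in range(len(path) - 1):
        path[i].children.append(path[i + 1])
        path[i + 1].parent = path[i]
        path[i + 1].length = lengths[i]
    start.parent = None
    start.length = None
    return start


def _suppress_unifurcations(root: TreeNode) -> None:
    """Splice out unlabeled internal nodes with a single child, summing the
    two branch lengths."""
    stack = list(root.children)
    while stack:
        node = stack.pop()
        if len(node.children) == 1 and node.label is None and node.parent is not None:
            only = node.children[0]
            only.length = (only.length or 0.0) + (node.length or 0.0)
            only.parent = node.parent
            node.parent.children[node.parent.children.index(node)] = only
            stack.append(only)
        else:
            stack.extend(node.children)


def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.read(path)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    tree.write(path)


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unweighted Robinson-Foulds distance via dendropy."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=a.to_newick(), schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    tb = dendropy.Tree.get(data=b.to_newick(), schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SubstModel:
    """Time-reversible substitution model over an arbitrary state alphabet.

    ``kind`` is ``"poisson_equal"`` (equal rates, equal frequencies),
    ``"empirical"`` (e.g. JTT), or ``"codon"``.  ``exchangeability`` is the
    symmetric matrix ``S`` with ``Q = S diag(pi)`` scaled to unit expected
    rate.  ``gamma_shape``/``n_rate_categories`` switch on discrete-gamma
    rate variation across sites.
    """

    kind: str
    exchangeability: np.ndarray
    frequencies: np.ndarray
    states: str | list[str] = AMINO_ACIDS
    gamma_shape: float | None = None
    n_rate_categories: int = 1

    def __post_init__(self) -> None:
        n = len(self.states)
        S = np.asarray(self.exchangeability, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (n, n):
            raise ValueError(f"exchangeability must be {n}x{n}")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if abs(pi.sum() - 1.0) > 1e-4:  # files carry rounded frequencies
            raise ValueError("frequencies must sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        self.frequencies = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()  # expected substitutions/site/unit time
        Q /= mu
        self.rate_matrix = Q
        # eigendecomposition of the symmetrized generator for exp(Qt)
        sq = np.sqrt(self.frequencies)
        B = (sq[:, None] * Q) / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigw = w
        self._left = U / sq[:, None] * 1.0      # D^{-1/2} U
        self._right = (U * sq[:, None]).T       # U^T D^{1/2}

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.states)}

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """Discrete-gamma category rates and weights (mean rate 1)."""
        k = self.n_rate_categories
        if self.gamma_shape is None or k == 1:
            return np.array([1.0]), np.array([1.0])
        a = self.gamma_shape
        from scipy.stats import gamma as gamma_dist
        bounds = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        # mean of X within each equal-probability bin, via the incomplete
        # gamma identity E[X; X<b] = P(a+1, a b) for mean-1 gamma
        upper = gammainc(a + 1, a * bounds[1:])
        lower = gammainc(a + 1, a * bounds[:-1])
        rates = (upper - lower) * k
        weights = np.full(k, 1.0 / k)
        rates = rates / (rates * weights).sum()
        return rates, weights

    def transition_matrix(self, t: float) -> np.ndarray:
        """``P(t) = exp(Qt)``; rows sum to one, ``P(0) = I``."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        P = (self._left * np.exp(self._eigw * t)) @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def poisson_model(n_states: int = 20, states: str | list[str] = AMINO_ACIDS,
                  gamma_shape: float | None = None, n_rate_categories: int = 1) -> SubstModel:
    S = np.ones((n_states, n_states))
    np.fill_diagonal(S, 0.0)
    return SubstModel(
        kind="poisson_equal", exchangeability=S,
        frequencies=np.full(n_states, 1.0 / n_states), states=states,
        gamma_shape=gamma_shape, n_rate_categories=n_rate_categories,
    )


def read_paml_matrix(source: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a PAML-format amino-acid rate file: 19 lower-triangle rows of
    exchangeabilities followed by the 20 equilibrium frequencies.

    ``source`` may be a file path or the file's text content.
    """
    text = str(source)
    if "\n" not in text and Path(text).is_file():
        text = Path(text).read_text()
    values: list[float] = []
    for line in text.splitlines():
        parts = line.split()
        try:
            row = [float(x) for x in parts]
        except ValueError:
            break  # trailing commentary
        values.extend(row)
    if len(values) < 190 + 20:
        raise ValueError("PAML matrix file is truncated")
    tri, freqs = values[:190], values[190:210]
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    return S, np.array(freqs)


def load_empirical_model(name: str = "JTT", gamma_shape: float | None = None,
                         n_rate_categories: int = 1) -> SubstModel:
    """Load a bundled empirical amino-acid model (currently JTT)."""
    fname = f"{name.lower()}.dat"
    ref = importlib.resources.files("bitterevo.data").joinpath(fname)
    if not ref.is_file():
        raise ValueError(f"no bundled matrix named {name!r}")
    S, pi = read_paml_matrix(ref.read_text())
    return SubstModel(kind="empirical", exchangeability=S, frequencies=pi,
                      states=AMINO_ACIDS, gamma_shape=gamma_shape,
                      n_rate_categories=n_rate_categories)


def transition_matrix(model: SubstModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)


# ---------------------------------------------------------------------------
# Likelihood by pruning
# ---------------------------------------------------------------------------

def encode_alignment(msa: SequenceSet, model: SubstModel,
                     tokenizer: Callable[[str], list[str]] | None = None
                     ) -> tuple[dict[str, np.ndarray], int]:
    """Map sequences to integer state rows; unknown/gap symbols become -1
    (missing data).  Returns (id -> int array, n_sites)."""
    idx = model.state_index()
    out: dict[str, np.ndarray] = {}
    n_sites = None
    for rid, seq in msa.records:
        tokens = tokenizer(seq) if tokenizer else list(seq)
        row = np.array([idx.get(tok, -1) for tok in tokens], dtype=np.int64)
        if n_sites is None:
            n_sites = len(row)
        elif len(row) != n_sites:
            raise ValueError("alignment rows differ in length")
        out[rid] = row
    return out, int(n_sites or 0)


def _compress_patterns(states: dict[str, np.ndarray], leaf_order: list[str]
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse identical alignment columns.  Returns (matrix of shape
    (n_leaves, n_patterns), pattern weights, site -> pattern index)."""
    M = np.stack([states[l] for l in leaf_order], axis=0)  # (leaves, sites)
    patterns, site_to_pat, counts = np.unique(
        M, axis=1, return_inverse=True, return_counts=True)
    return patterns, counts.astype(float), site_to_pat


class _PruningWorkspace:
    """Shared state for likelihood / ASR passes on a fixed (tree, data, model)."""

    def __init__(self, tree: PhyloTree, msa: SequenceSet, model: SubstModel,
                 tokenizer: Callable[[str], list[str]] | None = None,
                 branch_rates: dict[int, float] | None = None):
        leaf_names = tree.leaf_labels
        missing = [l for l in leaf_names if l not in msa]
        if missing:
            raise ValueError(f"leaves missing from alignment: {missing}")
        states, self.n_sites = encode_alignment(msa.subset(leaf_names), model, tokenizer)
        self.tree = tree
        self.model = model
        self.nodes = tree.postorder()
        self.patterns, self.weights, self.site_to_pat = _compress_patterns(states, leaf_names)
        self.leaf_row = {l: i for i, l in enumerate(leaf_names)}
        self.n_pat = self.patterns.shape[1]
        self.branch_rates = branch_rates or {}
        self.rates, self.rate_weights = model.rate_categories()

    def branch_length(self, node: TreeNode) -> float:
        t = node.length or 0.0
        return t * self.branch_rates.get(node.index, 1.0)

    def transition(self, node: TreeNode, rate: float) -> np.ndarray:
        return self.model.transition_matrix(self.branch_length(node) * rate)

    def leaf_partial(self, node: TreeNode) -> np.ndarray:
        n = self.model.n_states
        obs = self.patterns[self.leaf_row[node.label]]  # (n_pat,)
        part = np.zeros((self.n_pat, n))
        known = obs >= 0
        part[known, obs[known]] = 1.0
        part[~known, :] = 1.0  # gaps / ambiguity: missing data
        return part

    def up_pass(self, rate: float) -> tuple[list[np.ndarray], np.ndarray]:
        """Post-order partial vectors with per-node rescaling.  Returns
        (partials per node, log-scale accumulator per pattern)."""
        partials: list[np.ndarray | None] = [None] * len(self.nodes)
        logscale = np.zeros(self.n_pat)
        for node in self.nodes:
            if node.is_leaf:
                partials[node.index] = self.leaf_partial(node)
            else:
                acc = np.ones((self.n_pat, self.model.n_states))
                for child in node.children:
                    P = self.transition(child, rate)
                    acc *= partials[child.index] @ P.T
                scale = acc.max(axis=1)
                scale[scale == 0] = 1.0
                acc /= scale[:, None]
                logscale += np.log(scale)
                partials[node.index] = acc
        return partials, logscale  # type: ignore[return-value]

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-pattern log-likelihood, mixed over rate categories."""
        pi = self.model.frequencies
        per_cat = np.empty((len(self.rates), self.n_pat))
        for c, rate in enumerate(self.rates):
            partials, logscale = self.up_pass(rate)
            root = partials[self.nodes[-1].index]
            per_cat[c] = np.log(np.maximum(root @ pi, 1e-300)) + logscale
        m = per_cat.max(axis=0)
        mix = np.log((self.rate_weights[:, None] * np.exp(per_cat - m)).sum(axis=0)) + m
        return mix

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods() @ self.weights)


def log_likelihood(tree: PhyloTree, msa: SequenceSet, model: SubstModel,
                   tokenizer: Callable[[str], list[str]] | None = None) -> float:
    """Total log-likelihood of the alignment on the tree under the model.

    Gaps and unrecognized symbols are treated as missing data.  For
    reversible models the value does not depend on root placement.
    """
    return _PruningWorkspace(tree, msa, model, tokenizer).log_likelihood()


# ---------------------------------------------------------------------------
# Distances and NJ
# ---------------------------------------------------------------------------

DEFAULT_DMAX = 10.0


def pairwise_distance(seq_a: str, seq_b: str, model: SubstModel,
                      d_max: float = DEFAULT_DMAX) -> float:
    """Evolutionary distance (substitutions/site) between two aligned rows.

    For the Poisson (equal-rate) model the closed-form correction
    ``d = -(n-1)/n * ln(1 - n/(n-1) * p)`` is used; for empirical models the
    two-sequence likelihood is maximized numerically.  Saturated pairs return
    ``d_max``.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    idx = model.state_index()
    pairs = [(idx[x], idx[y]) for x, y in zip(seq_a, seq_b) if x in idx and y in idx]
    if not pairs:
        raise ValueError("no co-ungapped columns between sequences")
    n = model.n_states
    p_hat = sum(1 for x, y in pairs if x != y) / len(pairs)
    if model.kind == "poisson_equal":
        frac = (n - 1) / n
        if p_hat >= frac:
            return d_max
        return float(-frac * np.log(1.0 - p_hat / frac))
    if p_hat == 0.0:
        return 0.0
    a_idx = np.array([x for x, _ in pairs])
    b_idx = np.array([y for _, y in pairs])
    pi = model.frequencies

    def neg_ll(t: float) -> float:
        P = model.transition_matrix(t)
        return -float(np.log(np.maximum(pi[a_idx] * P[a_idx, b_idx], 1e-300)).sum())

    res = minimize_scalar(neg_ll, bounds=(1e-8, d_max), method="bounded",
                          options={"xatol": 1e-8})
    d = float(res.x)
    if d >= d_max - 1e-6:
        return d_max
    return d


def distance_matrix(msa: SequenceSet, model: SubstModel) -> tuple[np.ndarray, list[str]]:
    ids = msa.ids
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pairwise_distance(msa.get(ids[i]), msa.get(ids[j]), model)
    return D, ids


def nj_tree(D: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Neighbor joining on a symmetric non-negative distance matrix.

    Negative estimated branch lengths are clamped to zero.  The result is
    unrooted (basal trifurcation).
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or D.shape[0] != len(labels):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    import skbio
    dm = skbio.DistanceMatrix(D, ids=list(labels))
    sk_tree = skbio.tree.nj(dm)
    buf = io.StringIO()
    sk_tree.write(buf)
    tree = PhyloTree.from_newick(buf.getvalue(), rooted=False)
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# Branch-length optimization
# ---------------------------------------------------------------------------

def optimize_branch_lengths(tree: PhyloTree, msa: SequenceSet, model: SubstModel,
                            tol: float = 1e-4, max_sweeps: int = 20,
                            max_branch: float = DEFAULT_DMAX) -> PhyloTree:
    """Maximum-likelihood branch lengths on a fixed topology.

    Coordinate ascent: Brent's method on each branch in turn until a full
    sweep improves the log-likelihood by less than ``tol``.  The likelihood
    is non-decreasing across sweeps.
    """
    tree = tree.copy()
    ws = _PruningWorkspace(tree, msa, model)
    nodes = [n for n in tree.postorder() if n.parent is not None]
    ll = ws.log_likelihood()
    for _ in range(max_sweeps):
        sweep_start = ll
        for node in nodes:
            current = node.length or 0.0

            def neg_ll(t: float) -> float:
                node.length = t
                return -ws.log_likelihood()

            res = minimize_scalar(neg_ll, bounds=(0.0, max_branch), method="bounded",
                                  options={"xatol": 1e-6})
            if -res.fun >= ll - 1e-12:
                node.length = float(res.x)
                ll = -res.fun
            else:  # numerical blip: keep the previous value
                node.length = current
        new_ll = ws.log_likelihood()
        converged = new_ll - sweep_start < tol
        ll = new_ll
        if converged:
            break
    return tree
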