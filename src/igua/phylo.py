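"""Substitution model, clonal trees, and ancestral-column likelihoods.

Somatic point mutation is modeled with the Jukes-Cantor substitution process
along a rooted clonal tree. Any tree ``T`` is factored as ``mu * T1`` where
``T1`` has unit mean branch length and the scalar rate ``mu`` is integrated
over a discrete grid during inference. Column likelihoods for each candidate
root nucleotide are computed by Felsenstein pruning, vectorized over
alignment columns; CDR3 columns may carry a doubled effective rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize

from .msa import GAP_CODE, QueryAlignment, encode


def jc_probability(q: str, a: str, lam: float, gap_penalty: float = 0.01) -> float:
    """Jukes-Cantor transition probability P(q | a, lambda).

    Gap arguments fall outside the substitution process; they return the
    fixed per-site indel probability used by the alignment scoring contract.
    """
    if lam < 0:
        raise ValueError(f"negative branch length {lam}")
    if q == "-" or a == "-":
        return gap_penalty
    e = math.exp(-4.0 * lam / 3.0)
    return 0.25 + 0.75 * e if q == a else 0.25 - 0.25 * e


def jc_matrix(lam: float) -> np.ndarray:
    """4x4 Jukes-Cantor transition matrix for branch length ``lam``."""
    if lam < 0:
        raise ValueError(f"negative branch length {lam}")
    e = math.exp(-4.0 * lam / 3.0)
    off = 0.25 * (1.0 - e)
    return np.full((4, 4), off) + np.eye(4) * (0.25 + 0.75 * e - off)


class Node:
    """Tree node; ``length`` is the branch above the node (None at the root)."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class CladeTree:
    """Rooted clonal tree; the root represents the unmutated ancestor."""

    root: Node
    is_unit_normalized: bool = False
    mu: Optional[float] = None

    def postorder(self) -> list[Node]:
        out: list[Node] = []

        def walk(node: Node) -> None:
            for c in node.children:
                walk(c)
            out.append(node)

        walk(self.root)
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> set[str]:
        return {n.name for n in self.leaves()}

    def edges(self) -> list[Node]:
        """Non-root nodes, i.e. one per branch, in stable postorder."""
        return [n for n in self.postorder() if n.parent is not None]

    def branch_lengths(self) -> np.ndarray:
        return np.array([n.length for n in self.edges()], dtype=float)

    def set_branch_lengths(self, lengths: Sequence[float]) -> None:
        for node, lam in zip(self.edges(), lengths):
            node.length = float(lam)

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def copy(self) -> "CladeTree":
        def dup(node: Node) -> Node:
            new = Node(node.name, node.length)
            for c in node.children:
                new.add(dup(c))
            return new

        return CladeTree(dup(self.root), self.is_unit_normalized, self.mu)

    def clade_lengths(self) -> dict[frozenset, float]:
        """Branch length keyed by the set of leaf labels under the branch."""
        out: dict[frozenset, float] = {}
        labels: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                labels[id(node)] = frozenset([node.name])
            else:
                labels[id(node)] = frozenset().union(
                    *(labels[id(c)] for c in node.children)
                )
            if node.parent is not None:
                out[labels[id(node)]] = float(node.length)
        return out


def palm_tree(
    query_ids: Sequence[str], root_stem: float = 1.0, frond_length: float = 1.0
) -> CladeTree:
    """Star topology: root --stem-- last common ancestor --fronds-- leaves.

    The palm tree is invariant under permutation of the query labels and is
    the initialization tree of the iterative algorithm.
    """
    if not query_ids:
        raise ValueError("palm_tree needs at least one query id")
    root = Node("root")
    lca = root.add(Node("lca", float(root_stem)))
    for qid in query_ids:
        lca.add(Node(qid, float(frond_length)))
    mean = (root_stem + frond_length * len(query_ids)) / (len(query_ids) + 1)
    return CladeTree(root, is_unit_normalized=abs(mean - 1.0) < 1e-9)


def unit_normalize(tree: CladeTree) -> tuple[CladeTree, float]:
    """Rescale to unit mean branch length; returns (T1, scale) with
    scale * T1 == tree."""
    lengths = tree.branch_lengths()
    scale = float(lengths.mean())
    if scale <= 0:
        raise ValueError("cannot unit-normalize a tree with zero total length")
    out = tree.copy()
    out.set_branch_lengths(lengths / scale)
    out.is_unit_normalized = True
    return out, scale


@dataclass
class MuGrid:
    """Discretized overall mutation rate with prior and (fitted) posterior."""

    values: np.ndarray
    prior: np.ndarray
    posterior: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        if np.any(np.diff(self.values) <= 0) or np.any(self.values <= 0):
            raise ValueError("mu grid values must be positive and strictly increasing")
        if abs(self.prior.sum() - 1.0) > 1e-9:
            raise ValueError("mu prior must sum to 1")

    @classmethod
    def log_spaced(cls, lo: float = 0.001, hi: float = 0.5, k: int = 25) -> "MuGrid":
        values = np.geomspace(lo, hi, k)
        return cls(values=values, prior=np.full(k, 1.0 / k))


def _leaf_rows(alignment: QueryAlignment, tree: CladeTree) -> dict[str, int]:
    tree_leaves = tree.leaf_labels()
    if tree_leaves != set(alignment.ids):
        raise ValueError(
            f"tree leaves {sorted(tree_leaves)} do not match query ids "
            f"{sorted(alignment.ids)}"
        )
    return {qid: i for i, qid in enumerate(alignment.ids)}


def root_partials(
    alignment: QueryAlignment,
    tree: CladeTree,
    mu: float = 1.0,
    cdr3_mask: Optional[np.ndarray] = None,
    cdr3_multiplier: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Felsenstein pruning over all columns at once.

    Returns (partial, logscale): the conditional likelihood of the column
    data given root state a is ``partial[i, a] * exp(logscale[i])``. Leaf
    gaps are treated as missing data. Columns in ``cdr3_mask`` use doubled
    branch lengths (the CDR3 rate heuristic).
    """
    row_of = _leaf_rows(alignment, tree)
    L = alignment.length
    mask = None
    if cdr3_mask is not None:
        mask = np.asarray(cdr3_mask, dtype=bool)
        if mask.shape != (L,):
            raise ValueError("cdr3_mask must be a boolean vector of length L")
        if not mask.any():
            mask = None

    partials: dict[int, np.ndarray] = {}
    scales: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            codes = alignment.matrix[row_of[node.name]]
            part = np.zeros((L, 4))
            nongap = codes != GAP_CODE
            part[nongap, codes[nongap].astype(int)] = 1.0
            part[~nongap] = 1.0
            scale = np.zeros(L)
        else:
            part = np.ones((L, 4))
            scale = np.zeros(L)
            for child in node.children:
                cp, cs = partials.pop(id(child)), scales.pop(id(child))
                lam = float(child.length) * mu
                contrib = cp @ jc_matrix(lam).T
                if mask is not None:
                    contrib[mask] = cp[mask] @ jc_matrix(cdr3_multiplier * lam).T
                part *= contrib
                scale += cs
            top = part.max(axis=1)
            safe = np.where(top > 0, top, 1.0)
            part /= safe[:, None]
            scale += np.log(np.where(top > 0, top, 1.0))
        partials[id(node)] = part
        scales[id(node)] = scale
    return partials[id(tree.root)], scales[id(tree.root)]


def root_log_profile(
    alignment: QueryAlignment,
    tree: CladeTree,
    mu: float = 1.0,
    cdr3_mask: Optional[np.ndarray] = None,
    cdr3_multiplier: float = 2.0,
) -> np.ndarray:
    """(L, 4) matrix of log P(column | root nucleotide)."""
    part, scale = root_partials(alignment, tree, mu, cdr3_mask, cdr3_multiplier)
    with np.errstate(divide="ignore"):
        return np.log(part) + scale[:, None]


@dataclass
class AncestorProfile:
    """Per-column values over {A, C, G, T} at the root.

    ``mode`` is ``"log_likelihood"`` (unnormalized, from pruning) or
    ``"posterior"`` (each column a probability distribution).
    """

    values: np.ndarray
    mode: str = "log_likelihood"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError("profile must be (L, 4)")
        if self.mode not in ("log_likelihood", "posterior"):
            raise ValueError(f"unknown profile mode {self.mode!r}")
        if self.mode == "posterior":
            if np.any(self.values < -1e-12):
                raise ValueError("posterior profile must be nonnegative")
            sums = self.values.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError("posterior profile columns must sum to 1")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def modal_sequence(self) -> str:
        return "".join("ACGT"[i] for i in self.values.argmax(axis=1))


def ancestor_profile(
    aligned_queries: QueryAlignment,
    tree: CladeTree,
    mu: float = 1.0,
    cdr3_mask: Optional[np.ndarray] = None,
    cdr3_multiplier: float = 2.0,
) -> AncestorProfile:
    """Column-wise root-state log likelihoods for the current tree and rate."""
    if aligned_queries.length == 0:
        raise ValueError("empty alignment")
    return AncestorProfile(
        root_log_profile(aligned_queries, tree, mu, cdr3_mask, cdr3_multiplier),
        "log_likelihood",
    )


def column_root_likelihood(
    tree: CladeTree, column: Mapping[str, str], root_state: str
) -> float:
    """Exact pruning likelihood of a single column given the root nucleotide."""
    aln = QueryAlignment.from_rows({qid: base for qid, base in column.items()})
    prof = root_log_profile(aln, tree)
    code = "ACGT".index(root_state)
    return float(np.exp(prof[0, code]))


def tree_log_likelihood(
    alignment: QueryAlignment,
    tree: CladeTree,
    root_sequence: str,
    mu: float = 1.0,
    cdr3_mask: Optional[np.ndarray] = None,
    cdr3_multiplier: float = 2.0,
) -> float:
    """Log likelihood of the alignment given a fixed root sequence."""
    codes = encode(root_sequence)
    if codes.shape[0] != alignment.length:
        raise ValueError("root sequence length must equal the alignment length")
    part, scale = root_partials(alignment, tree, mu, cdr3_mask, cdr3_multiplier)
    per_col = np.empty(alignment.length)
    nongap = codes != GAP_CODE
    vals = part[np.arange(alignment.length), np.where(nongap, codes, 0).astype(int)]
    with np.errstate(divide="ignore"):
        per_col = np.where(
            nongap, np.log(np.maximum(vals, 1e-320)), np.log(part.mean(axis=1))
        )
    return float((per_col + scale).sum())


# ---------------------------------------------------------------------------
# Distance-based tree estimation (internal stand-in for an external ML tree;
# a newick file can be imported instead).
# ---------------------------------------------------------------------------


def jc_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Jukes-Cantor corrected distance between two aligned code vectors,
    ignoring columns where either has a gap."""
    usable = (a != GAP_CODE) & (b != GAP_CODE)
    n = int(usable.sum())
    if n == 0:
        return 0.0
    p = float((a[usable] != b[usable]).mean())
    p = min(p, 0.74)
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def neighbor_joining(
    labels: Sequence[str], dist: np.ndarray
) -> Node:
    """Deterministic neighbor joining; returns the final trifurcating node.

    Ties in the Q criterion are broken toward the lexicographically lowest
    (sorted) pair of subtree ids so the result is order-independent.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = {i: Node(labels[i]) for i in range(n)}
    keys = {i: labels[i] for i in range(n)}
    D = {(i, j): float(dist[i, j]) for i in range(n) for j in range(n) if i != j}
    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[(i, j)] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[(i, j)] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                if best is None or (q, tie) < (best[0], best[1]):
                    best = (q, tie, i, j)
        _, _, i, j = best
        dij = D[(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        ni, nj = nodes.pop(i), nodes.pop(j)
        ni.length, nj.length = max(li, 0.0), max(lj, 0.0)
        parent.add(ni)
        parent.add(nj)
        nodes[next_id] = parent
        keys[next_id] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            D[(next_id, k)] = D[(k, next_id)] = max(
                0.5 * (D[(i, k)] + D[(j, k)] - dij), 0.0
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    i, j, k = sorted(active, key=lambda x: keys[x])
    center = Node()
    dij, dik, djk = D[(i, j)], D[(i, k)], D[(j, k)]
    li = max(0.5 * (dij + dik - djk), 0.0)
    lj = max(0.5 * (dij + djk - dik), 0.0)
    lk = max(0.5 * (dik + djk - dij), 0.0)
    for idx, lam in ((i, li), (j, lj), (k, lk)):
        node = nodes.pop(idx)
        node.length = lam
        center.add(node)
    return center


def _reroot_at_leaf(unrooted: Node, leaf_name: str) -> Node:
    """Re-root an unrooted (trifurcating) tree at the named leaf.

    The leaf becomes the root node and its pendant edge is inherited by its
    former parent, giving a rooted tree whose root has a single child (the
    stem), as in the palm tree.
    """

    def find(node: Node) -> Optional[Node]:
        if node.is_leaf and node.name == leaf_name:
            return node
        for c in node.children:
            hit = find(c)
            if hit is not None:
                return hit
        return None

    leaf = find(unrooted)
    if leaf is None:
        raise ValueError(f"leaf {leaf_name!r} not found")

    def invert_parent(parent: Node, coming_from: Node, length: float) -> Node:
        new = Node(parent.name, length)
        for c in parent.children:
            if c is coming_from:
                continue
            new.add(_copy_subtree(c))
        if parent.parent is not None:
            new.add(invert_parent(parent.parent, parent, parent.length))
        return new

    root = Node(leaf.name)
    root.add(invert_parent(leaf.parent, leaf, leaf.length))
    return root


def _copy_subtree(node: Node) -> Node:
    new = Node(node.name, node.length)
    for c in node.children:
        new.add(_copy_subtree(c))
    return new


_ROOT_TAXON = "__UA_ROOT__"


def estimate_tree(
    aligned_queries: QueryAlignment,
    root_sequence: str,
    cdr3_mask: Optional[np.ndarray] = None,
    optimize_lengths: bool = True,
    cdr3_multiplier: float = 2.0,
) -> CladeTree:
    """Estimate a rooted clonal tree with the candidate ancestor at the root.

    Neighbor joining on Jukes-Cantor distances (ancestor included as a taxon),
    re-rooted at the ancestor, then branch lengths refined by maximizing the
    Jukes-Cantor likelihood with the topology fixed. Deterministic given the
    input order.
    """
    root_codes = encode(root_sequence)
    if root_codes.shape[0] != aligned_queries.length:
        raise ValueError("root sequence length must equal the alignment length")
    ids = list(aligned_queries.ids)
    mat = np.vstack([aligned_queries.matrix, root_codes[None, :]])
    labels = ids + [_ROOT_TAXON]
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = jc_distance(mat[i], mat[j])

    if n == 2:
        root = Node("root")
        lca = root.add(Node("lca", max(dist[0, 1] / 2, 0.0)))
        lca.add(Node(ids[0], max(dist[0, 1] / 2, 0.0)))
        tree = CladeTree(root)
    else:
        unrooted = neighbor_joining(labels, dist)
        rooted = _reroot_at_leaf(unrooted, _ROOT_TAXON)
        rooted.name = "root"
        tree = CladeTree(rooted)

    if optimize_lengths and aligned_queries.n_queries >= 2:
        tree = optimize_branch_lengths(
            tree, aligned_queries, root_sequence, cdr3_mask, cdr3_multiplier
        )
    return tree


def optimize_branch_lengths(
    tree: CladeTree,
    alignment: QueryAlignment,
    root_sequence: str,
    cdr3_mask: Optional[np.ndarray] = None,
    cdr3_multiplier: float = 2.0,
    max_branch: float = 5.0,
) -> CladeTree:
    """Refine branch lengths by L-BFGS-B on the fixed-topology JC likelihood."""
    work = tree.copy()
    x0 = np.clip(work.branch_lengths(), 1e-4, max_branch)

    def objective(x: np.ndarray) -> float:
        work.set_branch_lengths(x)
        return -tree_log_likelihood(
            alignment, work, root_sequence, 1.0, cdr3_mask, cdr3_multiplier
        )

    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(1e-8, max_branch)] * len(x0),
        options={"maxiter": 80},
    )
    work.set_branch_lengths(res.x)
    return work


# ---------------------------------------------------------------------------
# Newick import/export
# ---------------------------------------------------------------------------


def to_newick(tree: CladeTree) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name and node.parent is not None:
                body += node.name
        if node.parent is not None:
            body += f":{node.length:.10g}"
        return body

    return fmt(tree.root) + ";"


def from_newick(text: str) -> CladeTree:
    dt = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> Node:
        node = Node(
            dnode.taxon.label if dnode.taxon is not None else dnode.label,
            dnode.edge.length if dnode.parent_node is not None else None,
        )
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    root = convert(dt.seed_node)
    if root.name is None:
        root.name = "root"
    return CladeTree(root)
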