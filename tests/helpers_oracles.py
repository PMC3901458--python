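"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: exhaustive enumeration of alignment
paths, of interior-node state combinations, and of rearrangement parameter
tuples. They share no code with the dynamic programs they check.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

from igua.germline import LibrarySet
from igua.junction import ScoreScheme
from igua.msa import QueryAlignment
from igua.phylo import CladeTree, jc_probability, root_log_profile
from igua.rearrangement import (
    PriorConfig,
    build_ancestor_sequence,
    iter_hypotheses,
    log_prior,
)

CODE = {b: i for i, b in enumerate("ACGT")}


def brute_best_alignment_score(
    frag: tuple[int, ...], scheme: ScoreScheme, mode: str
) -> float:
    """Maximum N-adjusted score over every monotone alignment path.

    Mirrors the DP contract: "left" anchors the first used column at 0 with
    an optional (free or deletion-charged) skip of leading germline bases;
    "free" may start at any column. Insertions may extend past the last
    germline base.
    """
    G, L = len(frag), scheme.length

    @lru_cache(maxsize=None)
    def rec(g: int, c: int) -> float:
        options = [0.0] if g == G else []
        if g < G:
            options.append(scheme.deletion + rec(g + 1, c))
            if c < L:
                options.append(scheme.match_adj[c, frag[g]] + rec(g + 1, c + 1))
        # a floating window opens with a germline base, never an insertion
        if c < L and (g > 0 or mode == "left"):
            options.append(scheme.insertion_adj[c] + rec(g, c + 1))
        return max(options)

    if mode == "left":
        best = -math.inf
        for skip in range(G + 1):
            cost = 0.0 if scheme.free_end_gaps else scheme.deletion * skip
            best = max(best, cost + rec(skip, 0))
        return best
    if mode == "free":
        return max(rec(0, c) for c in range(L + 1))
    raise ValueError(mode)


def brute_column_root_likelihood(
    tree: CladeTree, column: dict[str, str], root_state: str
) -> float:
    """Sum over every combination of states at non-root, non-fixed nodes."""
    nodes = [n for n in tree.postorder() if n.parent is not None]
    free_nodes = [
        n for n in nodes if (not n.is_leaf) or column[n.name] == "-"
    ]
    total = 0.0
    states: dict[int, str] = {id(tree.root): root_state}
    for combo in itertools.product("ACGT", repeat=len(free_nodes)):
        for node, s in zip(free_nodes, combo):
            states[id(node)] = s
        for node in nodes:
            if node.is_leaf and column[node.name] != "-":
                states[id(node)] = column[node.name]
        prob = 1.0
        for node in nodes:
            prob *= jc_probability(
                states[id(node)], states[id(node.parent)], node.length
            )
        total += prob
    return total


def exhaustive_bayes_posterior(
    alignment: QueryAlignment,
    library: LibrarySet,
    tree: CladeTree,
    mu: float,
    pconf: PriorConfig,
) -> tuple[np.ndarray, dict[str, dict[str, float]]]:
    """Posterior by full enumeration of rearrangement tuples.

    Every (V, J, trims, n) tuple whose assembled ancestor matches the
    alignment length contributes prior x column-likelihood mass; returns the
    per-position posterior and the V/J segment posteriors.
    """
    L = alignment.length
    prof = root_log_profile(alignment, tree, mu)
    entries: list[tuple[float, str, str, str]] = []
    for params in iter_hypotheses(library, pconf):
        alpha = build_ancestor_sequence(params, library, validate=False)
        if len(alpha) != L:
            continue
        ll = log_prior(params, library, pconf)
        ll += sum(prof[i, CODE[b]] for i, b in enumerate(alpha))
        entries.append((ll, alpha, params.v_id, params.j_id))
    assert entries, "no tuple matches the alignment length"
    lls = np.array([e[0] for e in entries])
    w = np.exp(lls - lls.max())
    w /= w.sum()
    post = np.zeros((L, 4))
    seg: dict[str, dict[str, float]] = {"V": {}, "J": {}}
    for weight, (_, alpha, v_id, j_id) in zip(w, entries):
        for i, b in enumerate(alpha):
            post[i, CODE[b]] += weight
        seg["V"][v_id] = seg["V"].get(v_id, 0.0) + weight
        seg["J"][j_id] = seg["J"].get(j_id, 0.0) + weight
    return post, seg
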