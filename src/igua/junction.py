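"""Dynamic-programming alignment of germline segments to the query MSA.

The scoring scheme is derived from the substitution model: aligning ancestor
base ``a`` to column ``i`` scores the log column likelihood ``m(i, a)``;
insertions and deletions carry a fixed per-site indel log penalty; and a
column attributed to a nontemplated N nucleotide scores
``N_i = log sum_x P(column_i | x) pi_N(x)``.

All DP scores here are *N-adjusted*: a segment alignment's score is its raw
log-likelihood contribution minus the N-score of the columns it occupies.
With that convention the full-hypothesis log likelihood decomposes as
``sum_i N_i + adj(V) + adj(D) + adj(J)``, so each segment can be aligned
independently (the paper-style maximum-score alignment per segment) and the
segment-overlap indicator ``f`` is applied afterwards on the chosen
placements.

V alignments are anchored at the 5' end of the MSA and J at the 3' end;
germline overhanging the observed fragment window is skipped free when
``free_end_gaps`` is on. D floats between them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .germline import GeneSegment, Role, trim_range
from .msa import QueryAlignment, encode  # re-exported container types
from .phylo import AncestorProfile
from .rearrangement import PriorConfig, d_trim_pairs, segment_fragment

__all__ = [
    "QueryAlignment",
    "ScoreScheme",
    "SegmentAlignment",
    "build_score_scheme",
    "align_segment",
    "junction_consistency",
]


@dataclass
class ScoreScheme:
    """Per-column log scores for one tree/rate setting.

    log_match[i, a]: log P(column_i | ancestor base a) from pruning.
    n_score[i]: N-nucleotide score N_i (log prior-weighted mixture).
    insertion[i]: gap-in-ancestor score per column.
    deletion: score per unmatched germline base.
    """

    log_match: np.ndarray
    n_score: np.ndarray
    insertion: np.ndarray
    deletion: float
    free_end_gaps: bool = True

    # derived, filled in __post_init__
    match_adj: np.ndarray = field(init=False)
    insertion_adj: np.ndarray = field(init=False)
    n_prefix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.log_match = np.asarray(self.log_match, dtype=float)
        self.n_score = np.asarray(self.n_score, dtype=float)
        self.insertion = np.asarray(self.insertion, dtype=float)
        L = self.log_match.shape[0]
        if self.n_score.shape != (L,) or self.insertion.shape != (L,):
            raise ValueError("scheme component shapes disagree")
        self.match_adj = self.log_match - self.n_score[:, None]
        self.insertion_adj = self.insertion - self.n_score
        self.n_prefix = np.concatenate([[0.0], np.cumsum(self.n_score)])

    @property
    def length(self) -> int:
        return self.log_match.shape[0]

    @property
    def n_total(self) -> float:
        return float(self.n_prefix[-1])


def build_score_scheme(
    profile: AncestorProfile,
    pi_n: Optional[dict[str, float]] = None,
    gap_penalty: float = 0.01,
    free_end_gaps: bool = True,
    nongap_counts: Optional[np.ndarray] = None,
) -> ScoreScheme:
    """Derive the alignment scoring scheme from a root likelihood profile.

    The insertion score for a column charges the per-site indel penalty once
    per query that carries a base there (an ancestor gap must explain every
    observed base in the column); with a single query this reduces to the
    plain per-site penalty.
    """
    if profile.mode != "log_likelihood":
        raise ValueError("score scheme needs a likelihood-mode profile")
    log_match = profile.values
    if pi_n is None:
        log_pi = np.full(4, math.log(0.25))
    else:
        log_pi = np.log([pi_n[b] for b in "ACGT"])
    n_score = logsumexp(log_match + log_pi[None, :], axis=1)
    gap = math.log(gap_penalty)
    if nongap_counts is None:
        nongap_counts = np.ones(profile.length)
    return ScoreScheme(
        log_match=log_match,
        n_score=n_score,
        insertion=gap * np.asarray(nongap_counts, dtype=float),
        deletion=gap,
        free_end_gaps=free_end_gaps,
    )


@dataclass
class SegmentAlignment:
    """Best-scoring alignment of one trimmed germline fragment.

    ``score`` is N-adjusted (see module docstring). ``start_col``/``end_col``
    is the inclusive column interval occupied; an empty placement is encoded
    as ``end_col < start_col``.
    """

    segment_id: str
    role: Role
    trims: tuple[int, ...]
    fragment: str
    score: float
    start_col: int
    end_col: int
    mode: str

    def column_map(self, scheme: ScoreScheme) -> dict[int, Optional[int]]:
        """Column -> fragment base code (None where the ancestor has a gap).

        Recovered by DP traceback; only needed for surviving hypotheses.
        """
        frag = encode(self.fragment)
        if self.mode == "right":
            rev = _traceback(frag[::-1], _reverse_scheme(scheme), "left")
            L = scheme.length
            return {
                L - 1 - col: (None if b is None else int(frag[::-1][b]))
                for col, b in rev.items()
            }
        tb = _traceback(frag, scheme, self.mode)
        return {col: (None if b is None else int(frag[b])) for col, b in tb.items()}

    def fragment_index_column(self, scheme: ScoreScheme, index: int) -> Optional[int]:
        """Column where fragment base ``index`` is placed, if matched."""
        frag = encode(self.fragment)
        if self.mode == "right":
            rev = _traceback(frag[::-1], _reverse_scheme(scheme), "left")
            inv = {b: col for col, b in rev.items() if b is not None}
            ri = len(frag) - 1 - index
            return scheme.length - 1 - inv[ri] if ri in inv else None
        tb = _traceback(frag, scheme, self.mode)
        inv = {b: col for col, b in tb.items() if b is not None}
        return inv.get(index)


def _cummax_with_arg(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Running maximum and, per position, the latest index achieving it."""
    running = np.maximum.accumulate(values)
    idx = np.arange(values.shape[0])
    cand = np.where(values == running, idx, -1)
    return running, np.maximum.accumulate(cand)


def _dp_rows(
    frag: np.ndarray, scheme: ScoreScheme, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Forward DP. Returns (S, START).

    S[g, c]: best adjusted score consuming ``g`` fragment bases and the
    column window ending at column ``c - 1``; for mode "left" the window is
    the prefix 0..c-1, for mode "free" it may start anywhere (START tracks
    the window start).
    """
    G, L = frag.shape[0], scheme.length
    NEG = -1e30
    S = np.full((G + 1, L + 1), NEG)
    START = np.zeros((G + 1, L + 1), dtype=np.int32)
    ci = np.concatenate([[0.0], np.cumsum(scheme.insertion_adj)])

    if mode == "free":
        S[0, :] = 0.0
        START[0, :] = np.arange(L + 1)
    else:
        S[0, 0] = 0.0
        # leading insertions before any germline base are legal
        run, arg = _cummax_with_arg(S[0, :] - ci)
        S[0, :] = ci + run
        START[0, :] = 0
        if scheme.free_end_gaps:
            skip = np.zeros(G + 1)
        else:
            skip = scheme.deletion * np.arange(G + 1)
        S[:, 0] = np.maximum(S[:, 0], skip)

    for g in range(1, G + 1):
        base = int(frag[g - 1])
        match = S[g - 1, :-1] + scheme.match_adj[:, base]
        delete = S[g - 1, :] + scheme.deletion
        row = delete.copy()
        row_start = START[g - 1, :].copy()
        better = np.empty(L + 1, dtype=bool)
        better[0] = False
        better[1:] = match >= delete[1:]
        row[1:] = np.where(better[1:], match, delete[1:])
        row_start[1:] = np.where(better[1:], START[g - 1, :-1], START[g - 1, 1:])
        if mode == "left":
            row[0] = max(row[0], 0.0 if scheme.free_end_gaps else scheme.deletion * g)
        # close under insertions (gap in ancestor), linear gap costs
        run, arg = _cummax_with_arg(row - ci)
        S[g, :] = ci + run
        START[g, :] = row_start[arg]
    return S, START


def _reverse_scheme(scheme: ScoreScheme) -> ScoreScheme:
    return ScoreScheme(
        log_match=scheme.log_match[::-1].copy(),
        n_score=scheme.n_score[::-1].copy(),
        insertion=scheme.insertion[::-1].copy(),
        deletion=scheme.deletion,
        free_end_gaps=scheme.free_end_gaps,
    )


def _best_alignment(
    frag: np.ndarray, scheme: ScoreScheme, mode: str
) -> tuple[float, int, int]:
    """(score, start_col, end_col) of the best full-fragment placement."""
    S, START = _dp_rows(frag, scheme, mode)
    last = S[-1, :]
    c = int(last.argmax())  # earliest (5'-most) end on ties
    return float(last[c]), int(START[-1, c]), c - 1


def _traceback(
    frag: np.ndarray, scheme: ScoreScheme, mode: str
) -> dict[int, Optional[int]]:
    """Column -> fragment index (None = insertion column) for the best path."""
    S, START = _dp_rows(frag, scheme, mode)
    g = frag.shape[0]
    c = int(S[g, :].argmax())
    out: dict[int, Optional[int]] = {}
    tol = 1e-7

    def close(a: float, b: float) -> bool:
        return abs(a - b) <= tol * max(1.0, abs(a), abs(b))

    while g > 0 or (mode == "left" and c > 0) or (mode == "free" and c > START[g, c]):
        # predecessor tests at (g, c); ordering match > delete > insert keeps
        # the gap count minimal on ties
        if g > 0 and c > 0 and close(
            S[g - 1, c - 1] + scheme.match_adj[c - 1, int(frag[g - 1])], S[g, c]
        ):
            out[c - 1] = g - 1
            g, c = g - 1, c - 1
            continue
        if g > 0 and close(S[g - 1, c] + scheme.deletion, S[g, c]):
            g = g - 1
            continue
        if c > 0 and close(S[g, c - 1] + scheme.insertion_adj[c - 1], S[g, c]):
            out[c - 1] = None
            c = c - 1
            continue
        if mode == "left" and g > 0 and c == 0:
            break  # free leading germline skip
        if mode == "free" and c == START[g, c] and (g == 0 or close(S[g, c], 0.0)):
            break
        # numerical fallback: prefer match, then delete, then insert
        candidates = []
        if g > 0 and c > 0:
            candidates.append(
                (S[g - 1, c - 1] + scheme.match_adj[c - 1, int(frag[g - 1])], "m")
            )
        if g > 0:
            candidates.append((S[g - 1, c] + scheme.deletion, "d"))
        if c > 0:
            candidates.append((S[g, c - 1] + scheme.insertion_adj[c - 1], "i"))
        if not candidates:
            break
        _, op = max(candidates, key=lambda t: t[0])
        if op == "m":
            out[c - 1] = g - 1
            g, c = g - 1, c - 1
        elif op == "d":
            g = g - 1
        else:
            out[c - 1] = None
            c = c - 1
    return out


def _dp_batch(
    frags: np.ndarray, scheme: ScoreScheme, mode: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the DP for a batch of equal-length fragments at once.

    Returns (scores, start_cols, end_cols), each of shape (K,).
    """
    K, G = frags.shape
    L = scheme.length
    NEG = -1e30
    ci = np.concatenate([[0.0], np.cumsum(scheme.insertion_adj)])
    idx = np.arange(L + 1)

    if mode == "free":
        S = np.zeros((K, L + 1))
        START = np.tile(idx, (K, 1)).astype(np.int32)
    else:
        S = np.full((K, L + 1), NEG)
        S[:, 0] = 0.0
        running = np.maximum.accumulate(S - ci[None, :], axis=1)
        S = ci[None, :] + running
        START = np.zeros((K, L + 1), dtype=np.int32)

    for g in range(1, G + 1):
        bases = frags[:, g - 1].astype(int)
        match = S[:, :-1] + scheme.match_adj[:, bases].T
        delete = S + scheme.deletion
        row = delete
        row_start = START.copy()
        better = match >= delete[:, 1:]
        row[:, 1:] = np.where(better, match, delete[:, 1:])
        row_start[:, 1:] = np.where(better, START[:, :-1], START[:, 1:])
        if mode == "left":
            anchor0 = 0.0 if scheme.free_end_gaps else scheme.deletion * g
            row[:, 0] = np.maximum(row[:, 0], anchor0)
        b = row - ci[None, :]
        running = np.maximum.accumulate(b, axis=1)
        cand = np.where(b == running, idx[None, :], -1)
        arg = np.maximum.accumulate(cand, axis=1)
        S = ci[None, :] + running
        START = np.take_along_axis(row_start, arg, axis=1)

    ends = S.argmax(axis=1)
    rows = np.arange(K)
    return S[rows, ends], START[rows, ends], ends - 1


def align_role(
    segments: Sequence[GeneSegment],
    scheme: ScoreScheme,
    config: Optional[PriorConfig] = None,
) -> list[SegmentAlignment]:
    """Best alignment per (segment, trim) across a whole role.

    V fragments are aligned anchored to the MSA 5' end, J fragments to the
    3' end, D fragments float between. Scores are N-adjusted. Fragments of
    equal length share one vectorized DP pass.
    """
    config = config or PriorConfig()
    items: list[tuple[GeneSegment, tuple[int, ...], str, str]] = []
    for segment in segments:
        if segment.role is Role.D:
            for r1, r2 in d_trim_pairs(segment, config):
                frag = segment_fragment(segment.sequence, Role.D, r1, r2)
                items.append((segment, (r1, r2), frag, "free"))
        else:
            mode = "left" if segment.role is Role.V else "right"
            lo, hi = trim_range(segment)
            for r in range(lo, hi + 1):
                frag = segment_fragment(segment.sequence, segment.role, r)
                items.append((segment, (r,), frag, mode))

    results: list[Optional[SegmentAlignment]] = [None] * len(items)
    rev_scheme: Optional[ScoreScheme] = None
    groups: dict[tuple[str, int], list[int]] = {}
    for i, (_, _, frag, mode) in enumerate(items):
        groups.setdefault((mode, len(frag)), []).append(i)

    L = scheme.length
    for (mode, _), members in groups.items():
        if mode == "right":
            if rev_scheme is None:
                rev_scheme = _reverse_scheme(scheme)
            frags = np.stack([encode(items[i][2])[::-1] for i in members])
            scores, rev_starts, rev_ends = _dp_batch(frags, rev_scheme, "left")
            empty = rev_ends < rev_starts
            starts = np.where(empty, L, L - 1 - rev_ends)
            ends = np.where(empty, L - 1, L - 1 - rev_starts)
        else:
            frags = np.stack([encode(items[i][2]) for i in members])
            scores, starts, ends = _dp_batch(frags, scheme, mode)
        for k, i in enumerate(members):
            segment, trims, frag, m = items[i]
            results[i] = SegmentAlignment(
                segment.segment_id, segment.role, trims, frag,
                float(scores[k]), int(starts[k]), int(ends[k]), m,
            )
    return results  # type: ignore[return-value]


def align_segment(
    segment: GeneSegment,
    scheme: ScoreScheme,
    config: Optional[PriorConfig] = None,
) -> list[SegmentAlignment]:
    """Best alignment per admissible trim value (pairs of trims for D)."""
    return align_role([segment], scheme, config)


def junction_consistency(
    v_end: int,
    j_start: int,
    d_interval: Optional[tuple[int, int]] = None,
) -> int:
    """Overlap indicator f: 1 iff the chosen placements do not overlap.

    Adjacent placements (empty N region) are allowed; for heavy chains the
    D interval must lie strictly between the V end and the J start.
    """
    if d_interval is None:
        return int(v_end < j_start)
    d_start, d_end = d_interval
    if d_end < d_start:
        return 0
    return int(v_end < d_start and d_end < j_start)
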