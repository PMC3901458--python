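"""Query multiple sequence alignment container and a built-in aligner.

The inference engine treats the query MSA as fixed. Somatic hypermutation
only rarely produces indels, so clonally related sequences are usually
already column-compatible; when they are not, a simple center-star aligner
(seeded by the longest query, pairwise alignments via Biopython) provides a
dependency-free default. A pre-computed MSA can always be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio import Align

GAP_CODE = 4
_CODE = {b: i for i, b in enumerate("ACGT")}
_CODE["-"] = GAP_CODE
_DECODE = np.array(list("ACGT-"))


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT/gap character {exc.args[0]!r} in sequence") from exc


def decode(codes: Iterable[int]) -> str:
    return "".join(_DECODE[c] for c in codes)


@dataclass
class QueryAlignment:
    """Aligned query set: ids plus an (n_queries, L) code matrix (4 = gap)."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix must be (n_queries, L) with one row per id")
        if self.matrix.shape[0] == 0:
            raise ValueError("alignment needs at least one query")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_queries(self) -> int:
        return self.matrix.shape[0]

    def row(self, qid: str) -> str:
        return decode(self.matrix[self.ids.index(qid)])

    def rows(self) -> dict[str, str]:
        return {qid: decode(r) for qid, r in zip(self.ids, self.matrix)}

    def column(self, i: int) -> dict[str, int]:
        return {qid: int(c) for qid, c in zip(self.ids, self.matrix[:, i])}

    @classmethod
    def from_rows(cls, rows: Mapping[str, str]) -> "QueryAlignment":
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"aligned rows must share one length, got {sorted(lengths)}")
        return cls(list(rows), np.stack([encode(s) for s in rows.values()]))


def align_queries(sequences: Mapping[str, str]) -> QueryAlignment:
    """Return a query MSA, center-star aligning only if lengths differ."""
    if len({len(s) for s in sequences.values()}) == 1:
        return QueryAlignment.from_rows(dict(sequences))
    return center_star_align(sequences)


def center_star_align(sequences: Mapping[str, str]) -> QueryAlignment:
    """Center-star MSA seeded by the longest sequence.

    Every query is pairwise-aligned to the center; gaps opened in the center
    by any pairwise alignment are merged into all rows.
    """
    ids = list(sequences)
    center_id = max(ids, key=lambda k: (len(sequences[k]), k))
    center = sequences[center_id]
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-2,
    )
    pairwise: dict[str, tuple[str, str]] = {}
    for qid in ids:
        if qid == center_id:
            pairwise[qid] = (center, center)
            continue
        aln = aligner.align(center, sequences[qid])[0]
        pairwise[qid] = (str(aln[0]), str(aln[1]))

    # Merged gap pattern: number of inserted columns after each center base.
    n = len(center)
    gaps_after = np.zeros(n + 1, dtype=int)
    for c_row, _ in pairwise.values():
        pos, run = 0, 0
        local = np.zeros(n + 1, dtype=int)
        for ch in c_row:
            if ch == "-":
                run += 1
            else:
                local[pos] = run
                run, pos = 0, pos + 1
        local[n] = run
        gaps_after = np.maximum(gaps_after, local)

    rows: dict[str, str] = {}
    for qid in ids:
        c_row, q_row = pairwise[qid]
        out: list[str] = []
        pos, run = 0, []
        for c_ch, q_ch in zip(c_row, q_row):
            if c_ch == "-":
                run.append(q_ch)
            else:
                out.append("".join(run) + "-" * (gaps_after[pos] - len(run)))
                out.append(q_ch)
                run, pos = [], pos + 1
        out.append("".join(run) + "-" * (gaps_after[n] - len(run)))
        # left-pad insert runs so rows stay rectangular
        rows[qid] = "".join(out)
    lengths = {len(r) for r in rows.values()}
    if len(lengths) != 1:  # pragma: no cover - defensive
        raise RuntimeError("center-star merge produced ragged rows")
    return QueryAlignment(ids, np.stack([encode(r) for r in rows.values()]))
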