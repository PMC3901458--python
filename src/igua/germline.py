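"""Germline V/(D)/J gene-segment libraries.

A library holds the gene segments a rearrangement can draw from, together
with the prior probability of each allele and the range of recombination
points allowed for each segment.

Priors follow the locus-uniform convention: every gene-segment locus carries
the same prior mass regardless of how many allelic variants it has, and
alleles within a locus are equiprobable. Known allele frequencies can replace
this scheme through a tab-separated override file.

Recombination points are stored as *trim counts* measured from the joining
end of the segment (V: 3' end; J: 5' end; D: one count per end). Zero means
the germline end is used intact, positive ``k`` removes ``k`` germline
nucleotides, and negative ``k`` (floored at -4) appends ``|k|`` P
nucleotides, i.e. the reverse complement of the terminal germline bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

from Bio import SeqIO

NUCLEOTIDES = "ACGT"

#: Most P nucleotides a single segment end may contribute.
P_MAX = 4


class Role(str, Enum):
    V = "V"
    D = "D"
    J = "J"


class LibraryError(ValueError):
    """Raised for malformed library files or invalid segments."""


_ID_RE = re.compile(r"^(?P<locus>[^*\s]+)\*(?P<allele>\S+)$")


def parse_segment_id(segment_id: str) -> tuple[str, str]:
    """Split an IMGT-style name such as ``IGHV4-34*01`` into (locus, allele)."""
    m = _ID_RE.match(segment_id)
    if m is None:
        raise LibraryError(
            f"cannot parse locus*allele from segment id {segment_id!r}"
        )
    return m.group("locus"), m.group("allele")


@dataclass(frozen=True)
class GeneSegment:
    """One germline gene segment.

    ``anchor`` is the 0-based index of the first nucleotide of the second
    invariant cysteine codon (V) or of the invariant tryptophan/phenylalanine
    codon (J); D segments have no anchor.
    """

    segment_id: str
    role: Role
    sequence: str
    anchor: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise LibraryError(f"{self.segment_id}: empty sequence")
        bad = set(self.sequence) - set(NUCLEOTIDES)
        if bad:
            raise LibraryError(
                f"{self.segment_id}: non-ACGT characters {sorted(bad)!r} "
                "(IUPAC ambiguity codes are not supported)"
            )
        if self.anchor is not None and not (
            0 <= self.anchor <= len(self.sequence) - 3
        ):
            raise LibraryError(
                f"{self.segment_id}: anchor {self.anchor} outside "
                f"[0, {len(self.sequence) - 3}]"
            )
        parse_segment_id(self.segment_id)

    @property
    def locus(self) -> str:
        return parse_segment_id(self.segment_id)[0]

    @property
    def allele(self) -> str:
        return parse_segment_id(self.segment_id)[1]


def trim_range(segment: GeneSegment) -> tuple[int, int]:
    """Closed interval [r_min, r_max] of allowed trim counts for a segment.

    r_min is -4 for every role (up to four P nucleotides). r_max never
    removes the invariant Cys/Trp codon: for V it is the number of germline
    nucleotides 3' of the cysteine codon, for J the number 5' of the
    tryptophan/phenylalanine codon. D segments may be trimmed entirely.
    """
    n = len(segment.sequence)
    if segment.role is Role.V:
        if segment.anchor is None:
            raise LibraryError(f"{segment.segment_id}: V segment lacks an anchor")
        return (-P_MAX, n - (segment.anchor + 3))
    if segment.role is Role.J:
        if segment.anchor is None:
            raise LibraryError(f"{segment.segment_id}: J segment lacks an anchor")
        return (-P_MAX, segment.anchor)
    return (-P_MAX, n)


def find_v_anchor(sequence: str) -> Optional[int]:
    """Locate the second invariant cysteine codon in a V segment.

    Returns the start of the 3'-most TGT/TGC codon, the conserved Cys that
    opens CDR3 in productive V segments.
    """
    for p in range(len(sequence) - 3, -1, -1):
        if sequence[p : p + 3] in ("TGT", "TGC"):
            return p
    return None


_J_MOTIF = re.compile(r"(?=(TGG|TTT|TTC)GG.(...)GG.)")


def find_j_anchor(sequence: str) -> Optional[int]:
    """Locate the invariant Trp/Phe codon in a J segment.

    Searches 5'->3' for the canonical W/F-G-X-G motif that closes CDR3.
    """
    m = _J_MOTIF.search(sequence)
    return m.start() if m else None


@dataclass
class GeneSegmentLibrary:
    """Segments of one role plus their allele-level prior probabilities."""

    role: Role
    segments: list[GeneSegment]
    allele_prior: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seg in self.segments:
            if seg.role is not self.role:
                raise LibraryError(
                    f"{seg.segment_id}: role {seg.role} in a {self.role} library"
                )
            if seg.segment_id in seen:
                raise LibraryError(f"duplicate segment id {seg.segment_id!r}")
            seen.add(seg.segment_id)
        if not self.allele_prior:
            self.allele_prior = locus_uniform_prior(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def get(self, segment_id: str) -> GeneSegment:
        for seg in self.segments:
            if seg.segment_id == segment_id:
                return seg
        raise KeyError(segment_id)

    @property
    def loci(self) -> list[str]:
        out: list[str] = []
        for seg in self.segments:
            if seg.locus not in out:
                out.append(seg.locus)
        return out


def locus_uniform_prior(segments: list[GeneSegment]) -> dict[str, float]:
    """Equal mass per locus, split equally among the locus's alleles."""
    by_locus: dict[str, list[str]] = {}
    for seg in segments:
        by_locus.setdefault(seg.locus, []).append(seg.segment_id)
    n_loci = len(by_locus)
    prior: dict[str, float] = {}
    for alleles in by_locus.values():
        for sid in alleles:
            prior[sid] = 1.0 / (n_loci * len(alleles))
    return prior


def read_prior_overrides(path: str | Path) -> dict[str, float]:
    """Read ``segment_id<TAB>weight`` lines; weights are normalized to sum 1."""
    weights: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LibraryError(f"{path}:{lineno}: expected 'segment_id<TAB>weight'")
        sid, w = parts
        weights[sid] = float(w)
    total = sum(weights.values())
    if total <= 0:
        raise LibraryError(f"{path}: override weights must have positive sum")
    return {sid: w / total for sid, w in weights.items()}


def load_library(
    path: str | Path,
    role: Role | str,
    anchor_overrides: Optional[dict[str, int]] = None,
    prior_overrides: Optional[str | Path] = None,
) -> GeneSegmentLibrary:
    """Load a germline FASTA into a :class:`GeneSegmentLibrary`.

    Headers must start with an IMGT-style ``locus*allele`` token. Anchors for
    V and J segments are auto-detected (invariant Cys codon / W-G-X-G motif)
    unless supplied in ``anchor_overrides``.
    """
    role = Role(role)
    anchor_overrides = anchor_overrides or {}
    segments: list[GeneSegment] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        segment_id = rec.id.split("|")[0]
        seq = str(rec.seq).upper().replace("U", "T")
        anchor: Optional[int] = None
        if role is not Role.D:
            if segment_id in anchor_overrides:
                anchor = anchor_overrides[segment_id]
            elif role is Role.V:
                anchor = find_v_anchor(seq)
            else:
                anchor = find_j_anchor(seq)
            if anchor is None:
                raise LibraryError(
                    f"{segment_id}: could not locate the invariant "
                    f"{'Cys' if role is Role.V else 'Trp/Phe'} anchor; "
                    "supply an anchor override"
                )
        try:
            segments.append(
                GeneSegment(segment_id=segment_id, role=role, sequence=seq, anchor=anchor)
            )
        except LibraryError as exc:
            raise LibraryError(f"record {rec.id!r}: {exc}") from exc
    if not segments:
        raise LibraryError(f"{path}: no FASTA records")
    prior = None
    if prior_overrides is not None:
        prior = read_prior_overrides(prior_overrides)
        missing = {s.segment_id for s in segments} - set(prior)
        if missing:
            raise LibraryError(f"prior overrides missing segments: {sorted(missing)}")
    lib = GeneSegmentLibrary(role=role, segments=segments)
    if prior is not None:
        lib.allele_prior = {s.segment_id: prior[s.segment_id] for s in segments}
    return lib


@dataclass
class LibrarySet:
    """The libraries needed for one chain type (D only for heavy chains)."""

    v: GeneSegmentLibrary
    j: GeneSegmentLibrary
    d: Optional[GeneSegmentLibrary] = None

    @property
    def chain(self) -> str:
        return "heavy" if self.d is not None else "light"

    def library(self, role: Role) -> GeneSegmentLibrary:
        if role is Role.V:
            return self.v
        if role is Role.J:
            return self.j
        if self.d is None:
            raise LibraryError("no D library loaded (light chain?)")
        return self.d
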