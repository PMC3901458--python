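"""Small synthetic germline library bundled for offline tests and demos.

The segments are synthetic (labelled with IMGT-style names but invented
sequences) and engineered so the standard anchor detectors work: every V ends
in a Cys codon (TGT) followed by six nucleotides, every J carries the
canonical W/F-G-X-G motif after a six-nucleotide 5' overhang. One V locus
(IGHV1-1) has two alleles differing at two positions, to exercise
allelic-ambiguity behaviour.
"""

from __future__ import annotations

from pathlib import Path

from .germline import GeneSegment, GeneSegmentLibrary, LibrarySet, Role

_V_TAIL = "TGTAGAGGA"  # Cys codon at index 36, six 3' nucleotides

_HEAVY_V = {
    "IGHV1-1*01": "CAGGTGCAGCTGGTGCAGTCTGGAGCAGAGGTGAAA" + _V_TAIL,
    # allele 02 differs from 01 at positions 4 (T->A) and 22 (G->T)
    "IGHV1-1*02": "CAGGAGCAGCTGGTGCAGTCTGTAGCAGAGGTGAAA" + _V_TAIL,
    "IGHV2-5*01": "GAGGTGCAGCTGTTGGAGTCTGGGGGAGGCTTGGTA" + _V_TAIL,
    "IGHV3-7*01": "CAGGTCACCTTGAAGGAGTCTGGTCCTGTGCTGGTG" + _V_TAIL,
    "IGHV4-9*01": "CAGCTGCAGCTGCAGGAGTCGGGCCCAGGACTGGTG" + _V_TAIL,
    "IGHV5-2*01": "GAAGTGCAGCTGTTGCAGTCCGGCTCAGGACTGGTA" + _V_TAIL,
}

_HEAVY_D = {
    "IGHD1-1*01": "GGTATAACTGGAACGATAAG",
    "IGHD2-2*01": "AGCATATTGTGGTGGTGACT",
    "IGHD3-3*01": "GTATTACGATTTTTGGAGTG",
    "IGHD4-4*01": "TGACTACAGTAACTACGCCC",
}

_HEAVY_J = {
    "IGHJ4-1*01": "ACTACT" + "TGGGGCCAAGGGACCACGGTC",
    "IGHJ5-1*01": "CCGACA" + "TGGGGCAGAGGCACCCTGGTC",
    "IGHJ6-1*01": "TACTAC" + "TGGGGTCGAGGAACCACCGTC",
}

_LIGHT_V = {
    "IGKV1-3*01": "GACATCCAGATGACCCAGTCTCCATCCTCCCTGTCT" + _V_TAIL,
    "IGKV2-8*01": "GATATTGTGATGACTCAGTCTCCACTCTCCCTGCCC" + _V_TAIL,
}

_LIGHT_J = {
    "IGKJ1*01": "CTCACT" + "TTCGGCCAAGGGACCAAGGTG",
    "IGKJ3*01": "ATCACA" + "TTCGGCCCTGGGACCAAAGTG",
}

_V_ANCHOR = 36
_J_ANCHOR = 6


def _library(records: dict[str, str], role: Role) -> GeneSegmentLibrary:
    anchor = {Role.V: _V_ANCHOR, Role.J: _J_ANCHOR, Role.D: None}[role]
    segments = [
        GeneSegment(sid, role, seq, anchor) for sid, seq in records.items()
    ]
    return GeneSegmentLibrary(role=role, segments=segments)


def toy_heavy_library() -> LibrarySet:
    return LibrarySet(
        v=_library(_HEAVY_V, Role.V),
        j=_library(_HEAVY_J, Role.J),
        d=_library(_HEAVY_D, Role.D),
    )


def toy_light_library() -> LibrarySet:
    return LibrarySet(v=_library(_LIGHT_V, Role.V), j=_library(_LIGHT_J, Role.J))


def write_toy_fasta(outdir: str | Path, chain: str = "heavy") -> dict[str, Path]:
    """Write the toy library as FASTA files (for CLI round-trip tests)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if chain == "heavy":
        sets = {"V": _HEAVY_V, "D": _HEAVY_D, "J": _HEAVY_J}
    else:
        sets = {"V": _LIGHT_V, "J": _LIGHT_J}
    paths: dict[str, Path] = {}
    for role, records in sets.items():
        path = outdir / f"toy_{chain}_{role}.fasta"
        with path.open("w") as fh:
            for sid, seq in records.items():
                fh.write(f">{sid}\n{seq}\n")
        paths[role] = path
    return paths
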