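import numpy as np
import pytest

from igua.germline import GeneSegment, GeneSegmentLibrary, LibrarySet, Role
from igua.toylib import toy_heavy_library, toy_light_library


@pytest.fixture
def heavy_lib() -> LibrarySet:
    return toy_heavy_library()


@pytest.fixture
def light_lib() -> LibrarySet:
    return toy_light_library()


def tiny_light_library() -> LibrarySet:
    """Two-allele V locus and two J loci with <=6 nt segments.

    Small enough that every rearrangement tuple can be enumerated; anchors
    are planted explicitly (TGT at V index 2, Trp codon at J index 0, so
    V trims run -4..1 and J trims -4..0).
    """
    v = GeneSegmentLibrary(
        role=Role.V,
        segments=[
            GeneSegment("X*01", Role.V, "ACTGTC", anchor=2),
            GeneSegment("X*02", Role.V, "GCTGTC", anchor=2),
        ],
    )
    j = GeneSegmentLibrary(
        role=Role.J,
        segments=[
            GeneSegment("Y*01", Role.J, "TGGAC", anchor=0),
            GeneSegment("Z*01", Role.J, "TGGTT", anchor=0),
        ],
    )
    return LibrarySet(v=v, j=j)


@pytest.fixture
def tiny_lib() -> LibrarySet:
    return tiny_light_library()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
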