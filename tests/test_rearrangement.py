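import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igua.germline import GeneSegment, GeneSegmentLibrary, LibrarySet, Role
from igua.rearrangement import (
    PriorConfig,
    RearrangementError,
    RearrangementParams,
    ancestor_prior_mass,
    build_ancestor_sequence,
    iter_hypotheses,
    log_prior,
    revcomp,
    segment_fragment,
)


def hairpin_p_nucleotides(seq: str, k: int, end: str) -> str:
    """Independent oracle: P nucleotides read the complement of the terminal
    bases walking inward from the hairpin, one at a time."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if end == "3":
        return "".join(comp[seq[-(i + 1)]] for i in range(k))
    return "".join(comp[seq[i]] for i in range(k))[::-1]


def make_light_lib(v_seq="ACGT", j_seq="TTAA") -> LibrarySet:
    v = GeneSegmentLibrary(
        Role.V, [GeneSegment("V*01", Role.V, v_seq, anchor=0)]
    )
    j = GeneSegmentLibrary(
        Role.J, [GeneSegment("J*01", Role.J, j_seq, anchor=len(j_seq) - 3)]
    )
    return LibrarySet(v=v, j=j)


class TestBuildAncestor:
    def test_plain_concatenation(self):
        lib = make_light_lib()
        p = RearrangementParams("V*01", "J*01", r_v=0, r_j=0, n1="GG")
        assert build_ancestor_sequence(p, lib) == "ACGTGGTTAA"

    def test_p_nucleotides_on_v(self):
        lib = make_light_lib()
        p = RearrangementParams("V*01", "J*01", r_v=-2, r_j=0, n1="")
        assert build_ancestor_sequence(p, lib) == "ACGTACTTAA"

    def test_p_nucleotides_match_hairpin_oracle(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=10))
            k = int(rng.integers(1, 5))
            assert segment_fragment(seq, Role.V, -k) == seq + hairpin_p_nucleotides(
                seq, k, "3"
            )
            got = segment_fragment(seq, Role.J, -k)
            assert got.endswith(seq)
            assert got[:k] == revcomp(seq[:k])

    def test_heavy_length_arithmetic(self, heavy_lib):
        """Trim bookkeeping for an RV=1, RD1=5, RD2=7, RJ=3 rearrangement."""
        v = heavy_lib.v.get("IGHV1-1*01")
        d = heavy_lib.d.get("IGHD1-1*01")
        j = heavy_lib.j.get("IGHJ4-1*01")
        p = RearrangementParams(
            v.segment_id, j.segment_id, r_v=1, r_j=3, n1="AC",
            d_id=d.segment_id, r_d1=5, r_d2=7, n2="G",
        )
        ua = build_ancestor_sequence(p, heavy_lib)
        expected = (
            (len(v.sequence) - 1) + 2 + (len(d.sequence) - 12) + 1
            + (len(j.sequence) - 3)
        )
        assert len(ua) == expected

    def test_p_extension_then_trim_is_identity(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=12))
            k = int(rng.integers(1, 5))
            extended = segment_fragment(seq, Role.V, -k)
            assert extended[: len(seq)] == seq
            assert segment_fragment(extended, Role.V, k) == seq

    def test_out_of_range_trim_rejected(self):
        lib = make_light_lib()
        with pytest.raises(RearrangementError):
            build_ancestor_sequence(
                RearrangementParams("V*01", "J*01", r_v=-5, r_j=0), lib
            )

    def test_d_overtrim_rejected(self):
        with pytest.raises(RearrangementError):
            segment_fragment("ACGTAC", Role.D, 4, 3)


class TestLogPrior:
    def test_product_of_uniform_factors(self, tiny_lib):
        cfg = PriorConfig(n_max=4)
        p = RearrangementParams("X*01", "Y*01", r_v=0, r_j=0, n1="")
        got = log_prior(p, tiny_lib, cfg)
        # allele priors: X locus split over 2 alleles -> 1/2; Y one of 2 loci
        # -> 1/2; trim ranges: V has 6 values, J has 5
        expected = math.log(0.5) + math.log(0.5) - math.log(6) - math.log(5)
        assert math.isclose(got, expected, rel_tol=1e-12)

    def test_each_n_base_costs_log_quarter(self, tiny_lib):
        cfg = PriorConfig(n_max=8)
        base = RearrangementParams("X*01", "Y*01", r_v=0, r_j=0, n1="")
        with_n = RearrangementParams("X*01", "Y*01", r_v=0, r_j=0, n1="GG")
        delta = log_prior(with_n, tiny_lib, cfg) - log_prior(base, tiny_lib, cfg)
        assert math.isclose(delta, 2 * math.log(0.25), rel_tol=1e-12)

    def test_n_beyond_cap_excluded(self, tiny_lib):
        cfg = PriorConfig(n_max=1)
        p = RearrangementParams("X*01", "Y*01", r_v=0, r_j=0, n1="GG")
        assert log_prior(p, tiny_lib, cfg) == -math.inf


class TestAncestorPriorMass:
    def test_unique_tuple_gets_normalized_prior(self):
        lib = make_light_lib(v_seq="AAAA", j_seq="CCCC")
        cfg = PriorConfig(n_max=0)
        # With n_max=0 every tuple is (r_v, r_j) only; a sequence generated
        # by exactly one tuple carries exactly one prior cell.
        alpha = segment_fragment("AAAA", Role.V, -2) + "CCCC"  # unique: has TT
        mass = ancestor_prior_mass(alpha, lib, cfg)
        n_v, n_j = 6, 6  # trims -4..1 on both segments
        assert math.isclose(mass, 1.0 / (n_v * n_j), rel_tol=1e-9)

    def test_ambiguous_junction_base_sums_two_tuples(self):
        """A base explainable as germline V or as an N nucleotide collects
        prior mass from both parameter tuples."""
        lib = make_light_lib(v_seq="AACG", j_seq="TTTT")
        cfg = PriorConfig(n_max=1)
        alpha = "AACGTTTT"
        tuples = [
            p for p in iter_hypotheses(lib, cfg)
            if build_ancestor_sequence(p, lib, validate=False) == alpha
        ]
        # e.g. (r_v=0, n='', r_j=0) and (r_v=1, n='G', r_j=0) both make alpha
        assert len(tuples) >= 2
        total = sum(math.exp(log_prior(p, lib, cfg)) for p in tuples)
        everything = sum(
            math.exp(log_prior(p, lib, cfg)) for p in iter_hypotheses(lib, cfg)
        )
        assert math.isclose(
            ancestor_prior_mass(alpha, lib, cfg), total / everything, rel_tol=1e-9
        )

    def test_base_absent_from_library_is_impossible(self):
        lib = make_light_lib(v_seq="AAAA", j_seq="CCCC")
        cfg = PriorConfig(n_max=0)
        assert ancestor_prior_mass("AAGGCCCC", lib, cfg) == 0.0

    def test_mass_sums_to_one_over_generable_set(self):
        lib = make_light_lib(v_seq="AAC", j_seq="GTT")
        cfg = PriorConfig(n_max=1)
        alphas = {
            build_ancestor_sequence(p, lib, validate=False)
            for p in iter_hypotheses(lib, cfg)
        }
        total = sum(ancestor_prior_mass(a, lib, cfg) for a in alphas)
        assert math.isclose(total, 1.0, rel_tol=1e-9)

    def test_budget_guard(self, heavy_lib):
        with pytest.raises(RearrangementError, match="budget"):
            ancestor_prior_mass("ACGT", heavy_lib, PriorConfig(n_max=30))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_roundtrip_params_regenerate_own_ancestor(seed):
    """Enumerating tuples that regenerate a built ancestor always finds the
    generating tuple itself."""
    from conftest import tiny_light_library
    from igua.simulate import simulate_rearrangement

    lib = tiny_light_library()
    cfg = PriorConfig(n_max=2)
    truth = simulate_rearrangement(lib, cfg, seed=seed, n_max_sim=2)
    matches = [
        p
        for p in iter_hypotheses(lib, cfg)
        if build_ancestor_sequence(p, lib, validate=False) == truth.ua
    ]
    assert truth.params in matches
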