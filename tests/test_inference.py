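import math

import numpy as np
import pytest

from igua.config import RunConfig
from igua.germline import GeneSegment, GeneSegmentLibrary, LibrarySet, Role
from igua.inference import (
    InferenceError,
    factorized_log_likelihood,
    infer_ua,
    pairwise_stats,
    position_posterior,
    posterior_over_hypotheses,
    probable_error,
)
from igua.junction import build_score_scheme
from igua.msa import QueryAlignment, encode
from igua.phylo import AncestorProfile, MuGrid, ancestor_profile, palm_tree
from igua.rearrangement import PriorConfig


def light_config(**kw):
    base = dict(chain="light", mu_lo=0.005, mu_hi=0.2, mu_k=5, max_iter=4)
    base.update(kw)
    return RunConfig(**base)


class TestProbableError:
    def test_point_masses_have_zero_error(self):
        prof = AncestorProfile(np.eye(4)[[0, 1, 2, 3, 0]], "posterior")
        vec, total = probable_error(prof)
        assert np.allclose(vec, 0.0)
        assert total == 0.0

    def test_uniform_column_is_three_quarters(self):
        prof = AncestorProfile(np.full((1, 4), 0.25), "posterior")
        vec, total = probable_error(prof)
        assert vec[0] == pytest.approx(0.75)

    def test_split_posterior_arithmetic(self):
        prof = AncestorProfile(np.array([[0.49, 0.49, 0.01, 0.01]]), "posterior")
        _, total = probable_error(prof)
        assert total == pytest.approx(0.51)

    def test_likelihood_mode_rejected(self):
        prof = AncestorProfile(np.zeros((3, 4)), "log_likelihood")
        with pytest.raises(ValueError):
            probable_error(prof)


class TestHypothesisPosterior:
    def test_single_allele_library_gets_posterior_one(self, tiny_lib):
        lib = LibrarySet(
            v=GeneSegmentLibrary(Role.V, [tiny_lib.v.get("X*01")]),
            j=GeneSegmentLibrary(Role.J, [tiny_lib.j.get("Y*01")]),
        )
        query = lib.v.get("X*01").sequence + "AG" + lib.j.get("Y*01").sequence
        aln = QueryAlignment.from_rows({"q1": query})
        hp = posterior_over_hypotheses(
            aln, lib, palm_tree(["q1"]),
            MuGrid.log_spaced(0.01, 0.1, 3), light_config(n_max=4),
        )
        assert hp.segment_posteriors["V"]["X*01"] == pytest.approx(1.0)
        assert hp.segment_posteriors["J"]["Y*01"] == pytest.approx(1.0)

    def test_symmetric_alleles_split_posterior_evenly(self):
        """Two V alleles, one informative site each, erased symmetrically:
        posterior 0.5 / 0.5 (the allelic-ambiguity regime)."""
        v = GeneSegmentLibrary(
            Role.V,
            [
                GeneSegment("X*01", Role.V, "AATGTCCC", anchor=2),
                GeneSegment("X*02", Role.V, "TATGTCCC", anchor=2),
            ],
        )
        j = GeneSegmentLibrary(
            Role.J, [GeneSegment("Y*01", Role.J, "TGGAAA", anchor=0)]
        )
        lib = LibrarySet(v=v, j=j)
        # queries disagree at the informative site 0, one vote each way
        q1 = "AATGTCCC" + "TGGAAA"
        q2 = "TATGTCCC" + "TGGAAA"
        aln = QueryAlignment.from_rows({"q1": q1, "q2": q2})
        hp = posterior_over_hypotheses(
            aln, lib, palm_tree(["q1", "q2"]),
            MuGrid.log_spaced(0.02, 0.2, 4), light_config(n_max=2),
        )
        assert hp.segment_posteriors["V"]["X*01"] == pytest.approx(0.5, abs=1e-9)
        assert hp.segment_posteriors["V"]["X*02"] == pytest.approx(0.5, abs=1e-9)
        prof = position_posterior(hp, PriorConfig(n_max=2))
        # the ambiguous column splits its mass between A and T
        assert prof.values[0, 0] == pytest.approx(prof.values[0, 3], rel=1e-6)
        vec, _ = probable_error(prof)
        assert vec[0] == pytest.approx(0.5, abs=0.01)

    def test_no_feasible_hypothesis_raises(self, tiny_lib):
        aln = QueryAlignment.from_rows({"q1": "ACG"})  # shorter than any V+J
        with pytest.raises(InferenceError):
            posterior_over_hypotheses(
                aln, tiny_lib, palm_tree(["q1"]),
                MuGrid.log_spaced(0.01, 0.1, 2),
                light_config(n_max=0, free_end_gaps=False, gap_penalty=1e-12),
            )

    def test_position_posterior_columns_sum_to_one(self, tiny_lib):
        query = tiny_lib.v.get("X*01").sequence + "C" + tiny_lib.j.get("Z*01").sequence
        aln = QueryAlignment.from_rows({"q1": query, "q2": query})
        hp = posterior_over_hypotheses(
            aln, tiny_lib, palm_tree(["q1", "q2"]),
            MuGrid.log_spaced(0.01, 0.1, 3), light_config(),
        )
        prof = position_posterior(hp)
        assert np.allclose(prof.values.sum(axis=1), 1.0, atol=1e-9)


class TestFactorizedLikelihood:
    def test_overlapping_placements_are_impossible(self, tiny_lib):
        from igua.junction import align_segment

        query = tiny_lib.v.get("X*01").sequence + tiny_lib.j.get("Y*01").sequence
        aln = QueryAlignment.from_rows({"q1": query})
        prof = ancestor_profile(aln, palm_tree(["q1"]), mu=0.05)
        scheme = build_score_scheme(prof)
        pconf = PriorConfig()
        v_alns = align_segment(tiny_lib.v.get("X*01"), scheme, pconf)
        j_alns = align_segment(tiny_lib.j.get("Y*01"), scheme, pconf)
        v_full = next(a for a in v_alns if a.trims == (-4,))  # longest fragment
        j_full = next(a for a in j_alns if a.trims == (-4,))
        assert v_full.end_col >= j_full.start_col  # they collide on purpose
        assert factorized_log_likelihood(
            v_full, j_full, scheme, tiny_lib, pconf
        ) == -math.inf

    def test_clean_join_decomposes_into_match_scores_and_priors(self, tiny_lib):
        query = tiny_lib.v.get("X*01").sequence + tiny_lib.j.get("Y*01").sequence
        aln = QueryAlignment.from_rows({"q1": query})
        prof = ancestor_profile(aln, palm_tree(["q1"]), mu=0.03)
        scheme = build_score_scheme(prof)
        pconf = PriorConfig(n_max=2)
        from igua.junction import align_segment

        v0 = next(
            a for a in align_segment(tiny_lib.v.get("X*01"), scheme, pconf)
            if a.trims == (0,)
        )
        j0 = next(
            a for a in align_segment(tiny_lib.j.get("Y*01"), scheme, pconf)
            if a.trims == (0,)
        )
        got = factorized_log_likelihood(v0, j0, scheme, tiny_lib, pconf)
        codes = encode(query)
        direct = sum(scheme.log_match[i, codes[i]] for i in range(len(query)))
        priors = (
            math.log(0.5) - math.log(6) + math.log(0.5) - math.log(5)
        )
        assert got == pytest.approx(direct + priors, rel=1e-9)


class TestEndToEnd:
    def test_clean_light_clone_recovers_input(self, tiny_lib):
        """Exact germline V+J join, no N, no mutations: the input is its own
        ancestor and the posterior concentrates on it."""
        ua = tiny_lib.v.get("X*01").sequence + tiny_lib.j.get("Y*01").sequence
        queries = {f"q{i}": ua for i in range(3)}
        res = infer_ua(queries, tiny_lib, light_config(n_max=4))
        assert res.modal_ua == ua
        assert res.total_probable_error < 0.05
        assert res.segment_posteriors["V"]["X*01"] > 0.99
        assert res.mutation_frequency == pytest.approx(0.0)

    def test_total_probable_error_invariant_to_query_order(self, tiny_lib):
        ua = tiny_lib.v.get("X*02").sequence + "A" + tiny_lib.j.get("Z*01").sequence
        qs = {"q1": ua, "q2": ua[:5] + "T" + ua[6:], "q3": ua[:9] + "C" + ua[10:]}
        r1 = infer_ua(qs, tiny_lib, light_config(n_max=4))
        r2 = infer_ua(dict(reversed(list(qs.items()))), tiny_lib, light_config(n_max=4))
        assert r1.total_probable_error == pytest.approx(
            r2.total_probable_error, rel=1e-6
        )

    def test_junction_n_length_reported(self, tiny_lib):
        # chosen so neither segment's P nucleotides can mimic the junction
        # (V P bases would start with G, J P bases end with A)
        n_region = "CTTT"
        ua = tiny_lib.v.get("X*01").sequence + n_region + tiny_lib.j.get("Y*01").sequence
        res = infer_ua({"q1": ua, "q2": ua}, tiny_lib, light_config(n_max=8))
        assert res.junction_summary["n1"]["length"] == len(n_region)
        assert res.junction_summary["n1"]["sequence"] == n_region


class TestPairwiseStats:
    def test_identical_pair(self):
        s = pairwise_stats({"a": "ACGT", "b": "ACGT"})
        assert (s.mean, s.sd, s.max) == (0.0, 0.0, 0)

    def test_hand_counted_triple(self):
        s = pairwise_stats({"a": "AAAA", "b": "AAAT", "c": "AATT"})
        assert s.mean == pytest.approx(4 / 3)
        assert s.max == 2
        assert s.n_pairs == 3
        assert s.sd == pytest.approx(np.std([1, 2, 1], ddof=1))

    def test_gap_columns_excluded(self):
        s = pairwise_stats({"a": "AC-T", "b": "ACG-"})
        assert s.mean == 0.0

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            pairwise_stats({"a": "ACGT"})
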