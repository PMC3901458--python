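import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers_oracles import brute_column_root_likelihood
from igua.msa import QueryAlignment
from igua.phylo import (
    AncestorProfile,
    CladeTree,
    Node,
    ancestor_profile,
    column_root_likelihood,
    estimate_tree,
    from_newick,
    jc_matrix,
    jc_probability,
    palm_tree,
    to_newick,
    unit_normalize,
)


class TestJukesCantor:
    def test_identity_at_zero_branch(self):
        assert jc_probability("A", "A", 0.0) == pytest.approx(1.0)
        assert jc_probability("A", "C", 0.0) == pytest.approx(0.0)

    def test_closed_form_value(self):
        expected = (1 - math.exp(-0.4 / 3)) / 4
        assert jc_probability("A", "G", 0.1) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.03121, abs=5e-6)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            jc_probability("A", "A", -0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.0, 10.0))
    def test_rows_stochastic_and_symmetric(self, lam):
        m = jc_matrix(lam)
        assert np.allclose(m.sum(axis=1), 1.0)
        assert np.allclose(m, m.T)


def chain_tree(lengths, leaf="q1"):
    root = Node("root")
    node = root
    for lam in lengths[:-1]:
        node = node.add(Node(None, lam))
    node.add(Node(leaf, lengths[-1]))
    return CladeTree(root)


class TestPruning:
    def test_single_leaf_zero_branch(self):
        tree = chain_tree([0.0])
        assert column_root_likelihood(tree, {"q1": "A"}, "A") == pytest.approx(1.0)
        assert column_root_likelihood(tree, {"q1": "A"}, "C") == pytest.approx(0.0)

    def test_matches_bruteforce_on_three_leaf_tree(self, rng):
        tree = palm_tree(["a", "b", "c"])
        tree.set_branch_lengths(rng.uniform(0.05, 1.5, size=4))
        column = {"a": "A", "b": "C", "c": "A"}
        for root_state in "ACGT":
            got = column_root_likelihood(tree, column, root_state)
            want = brute_column_root_likelihood(tree, column, root_state)
            assert got == pytest.approx(want, rel=1e-9)

    def test_long_branch_limit_is_stationary(self):
        tree = palm_tree(["a", "b", "c"])
        tree.set_branch_lengths([50.0] * 4)
        got = column_root_likelihood(tree, {"a": "A", "b": "A", "c": "A"}, "G")
        assert got == pytest.approx(0.25**3, rel=1e-6)

    def test_gap_leaf_is_missing_data(self):
        tree = palm_tree(["a", "b"])
        full = column_root_likelihood(tree, {"a": "A", "b": "-"}, "A")
        single = column_root_likelihood(
            CladeTree(chain_tree([1.0, 1.0]).root), {"q1": "A"}, "A"
        )
        assert full == pytest.approx(single, rel=1e-9)

    def test_pulley_principle_on_root_marginal(self):
        """With a uniform root prior the marginal likelihood depends only on
        the total path length, not on where the root splits an edge."""

        def marginal(l1, l2):
            tree = chain_tree([l1, l2])
            return sum(
                0.25 * column_root_likelihood(tree, {"q1": "A"}, s) for s in "ACGT"
            )

        assert marginal(0.3, 0.7) == pytest.approx(marginal(0.9, 0.1), rel=1e-12)


class TestTrees:
    def test_palm_tree_three_ids(self):
        tree = palm_tree(["a", "b", "c"])
        assert len(tree.edges()) == 4
        assert all(e.length == 1.0 for e in tree.edges())
        assert tree.is_unit_normalized

    def test_palm_tree_single_id_is_chain(self):
        tree = palm_tree(["only"])
        assert [n.name for n in tree.leaves()] == ["only"]
        assert len(tree.edges()) == 2

    def test_palm_tree_edge_count(self):
        tree = palm_tree([f"q{i}" for i in range(7)])
        assert len(tree.leaves()) == 7
        assert len(tree.edges()) == 8

    def test_unit_normalize_examples(self):
        tree = palm_tree(["a", "b", "c"])  # (1,1,1,1)
        out, scale = unit_normalize(tree)
        assert scale == pytest.approx(1.0)
        tree.set_branch_lengths([2.0, 4.0, 2.0, 4.0])
        out, scale = unit_normalize(tree)
        assert scale == pytest.approx(3.0)
        assert np.allclose(out.branch_lengths(), [2 / 3, 4 / 3, 2 / 3, 4 / 3])

    def test_unit_normalize_roundtrip_and_idempotence(self, rng):
        tree = palm_tree(["a", "b", "c", "d"])
        lengths = rng.uniform(0.01, 3.0, size=5)
        tree.set_branch_lengths(lengths)
        out, scale = unit_normalize(tree)
        assert np.allclose(out.branch_lengths() * scale, lengths, atol=1e-12)
        again, scale2 = unit_normalize(out)
        assert scale2 == pytest.approx(1.0)
        assert np.allclose(again.branch_lengths(), out.branch_lengths())

    def test_unit_normalize_rejects_zero_tree(self):
        tree = palm_tree(["a", "b"])
        tree.set_branch_lengths([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            unit_normalize(tree)

    def test_newick_roundtrip(self):
        tree = palm_tree(["a", "b", "c"])
        tree.set_branch_lengths([0.5, 1.5, 2.5, 3.5])
        back = from_newick(to_newick(tree))
        assert back.leaf_labels() == {"a", "b", "c"}
        assert sorted(n.length for n in back.edges()) == pytest.approx(
            [0.5, 1.5, 2.5, 3.5]
        )


class TestAncestorProfile:
    def test_identical_queries_vote_for_shared_base(self):
        aln = QueryAlignment.from_rows({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        prof = ancestor_profile(aln, palm_tree(["a", "b", "c"]), mu=0.01)
        assert prof.modal_sequence() == "ACGT"

    def test_balanced_column_is_symmetric(self):
        aln = QueryAlignment.from_rows({"a": "A", "b": "A", "c": "C", "d": "C"})
        prof = ancestor_profile(aln, palm_tree(["a", "b", "c", "d"]), mu=0.1)
        assert prof.values[0, 0] == pytest.approx(prof.values[0, 1], rel=1e-9)

    def test_matches_column_root_likelihood(self, rng):
        rows = {"a": "ACGA", "b": "ACCT", "c": "GCGT"}
        aln = QueryAlignment.from_rows(rows)
        tree = palm_tree(["a", "b", "c"])
        tree.set_branch_lengths(rng.uniform(0.05, 0.8, size=4))
        prof = ancestor_profile(aln, tree)
        for i in range(4):
            column = {q: rows[q][i] for q in rows}
            for k, state in enumerate("ACGT"):
                want = column_root_likelihood(tree, column, state)
                assert math.exp(prof.values[i, k]) == pytest.approx(want, rel=1e-9)

    def test_posterior_mode_validation(self):
        with pytest.raises(ValueError):
            AncestorProfile(np.array([[0.5, 0.5, 0.1, 0.1]]), "posterior")


class TestEstimateTree:
    def test_queries_equal_root_give_zero_lengths(self):
        aln = QueryAlignment.from_rows({"a": "ACGTACGT", "b": "ACGTACGT"})
        tree = estimate_tree(aln, "ACGTACGT", optimize_lengths=False)
        assert tree.total_length() == pytest.approx(0.0, abs=1e-9)

    def test_equidistant_queries_are_symmetric(self):
        root = "AAAAAAAAAAAA"
        aln = QueryAlignment.from_rows(
            {"a": "AAAAAAAAAAAC", "b": "AAAAAAAAAAAG"}
        )
        tree = estimate_tree(aln, root)
        lengths = {n.name: n.length for n in tree.postorder() if n.is_leaf}
        assert lengths["a"] == pytest.approx(lengths["b"], rel=1e-4)

    def test_recovers_simulated_topology_at_low_rate(self):
        """Clades of an 8-leaf simulated clone are recovered in most seeds."""
        from igua.simulate import simulate_shm_clone
        from igua.simulate import SimulationTruth
        from igua.rearrangement import RearrangementParams

        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ua = "".join(rng.choice(list("ACGT"), size=400))
            truth = SimulationTruth(
                params=RearrangementParams("X*01", "Y*01", 0, 0),
                ua=ua,
                seed=seed,
            )
            clone = simulate_shm_clone(
                truth, 8, 0.02, seed=seed, topology="birth"
            )
            aln = QueryAlignment.from_rows(clone.sequences)
            est = estimate_tree(aln, ua, optimize_lengths=False)

            def clades(tree):
                out = set()
                for key in tree.clade_lengths():
                    if 1 < len(key) < 8:
                        out.add(key)
                return out

            true_clades = clades(clone.tree)
            if clades(est) == true_clades:
                hits += 1
        assert hits >= 3
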