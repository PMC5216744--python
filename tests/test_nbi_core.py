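"""Diffusion engine: transfer matrix, two-step spreading, standardisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smirnbi.graph_model import build_adjacency
from smirnbi.nbi_core import (
    build_transfer_matrix,
    diffuse,
    filter_by_threshold,
    score_all_queries,
    score_query,
    standardize_scores,
)

from conftest import random_bipartite, spread_resources_literally


class TestTransferMatrix:
    def test_toy_t1_row_normalisation(self, toy_t1):
        B = build_transfer_matrix(build_adjacency(toy_t1)).B
        # m2 (index 3) is linked to s1 and s2: equal split
        assert B[3].tolist() == [0.5, 0.5, 0, 0, 0]
        # m1 (index 2) is linked only to s1
        assert B[2].tolist() == [1, 0, 0, 0, 0]

    def test_rows_sum_to_one_or_zero(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            A = build_adjacency(random_bipartite(rng))
            B = build_transfer_matrix(A).B
            sums = B.sum(axis=1)
            assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))
            assert ((B > 0) <= (A > 0)).all()

    def test_isolated_node_row_stays_zero(self):
        A = np.array([[0.0, 1, 0], [1, 0, 0], [0, 0, 0]])
        B = build_transfer_matrix(A).B
        assert (B[2] == 0).all()

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            build_transfer_matrix(np.zeros((2, 3)))


class TestDiffuse:
    def test_matches_literal_spreading_on_random_networks(self):
        """Matrix formula F = A B^2 vs a node-by-node spreading simulation."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            net = random_bipartite(rng)
            A = build_adjacency(net)
            F = diffuse(A, build_transfer_matrix(A))
            for q in range(A.shape[0]):
                expected = spread_resources_literally(A, q)
                assert np.abs(F[q] - expected).max() < 1e-12

    def test_conservation_row_sums_equal_degrees(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            net = random_bipartite(rng)
            A = build_adjacency(net)
            F = diffuse(A, build_transfer_matrix(A))
            np.testing.assert_allclose(F.sum(axis=1), A.sum(axis=1), atol=1e-9)

    def test_mass_stays_on_opposite_class(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            net = random_bipartite(rng)
            m = net.n_molecules
            A = build_adjacency(net)
            F = diffuse(A, build_transfer_matrix(A))
            assert (F[:m, :m] == 0).all()
            assert (F[m:, m:] == 0).all()
            assert (F >= 0).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        net = random_bipartite(rng)
        A = build_adjacency(net)
        F = diffuse(A, build_transfer_matrix(A))
        perm = rng.permutation(A.shape[0])
        Ap = A[np.ix_(perm, perm)]
        Fp = diffuse(Ap, build_transfer_matrix(Ap))
        np.testing.assert_allclose(Fp, F[np.ix_(perm, perm)], atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            diffuse(np.zeros((2, 2)), np.zeros((3, 3)))


class TestStandardizeScores:
    def test_toy_t1_values(self):
        std, degenerate = standardize_scores(np.array([0.75, 1.0, 0.25]))
        np.testing.assert_allclose(std, [2 / 3, 1.0, 0.0])
        assert not degenerate

    def test_constant_vector_degenerates_to_zero(self):
        std, degenerate = standardize_scores(np.array([0.5, 0.5]))
        assert std.tolist() == [0.0, 0.0] and degenerate

    def test_zero_one_is_fixed_point(self):
        std, _ = standardize_scores(np.array([0.0, 1.0]))
        assert std.tolist() == [0.0, 1.0]

    def test_empty_vector_passes_through(self):
        std, degenerate = standardize_scores(np.array([]))
        assert std.size == 0 and not degenerate

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=30))
    def test_range_invariant(self, raw):
        std, degenerate = standardize_scores(np.array(raw))
        assert (std >= 0).all() and (std <= 1).all()
        if not degenerate:
            assert std.max() == 1.0 and std.min() == 0.0


class TestScoreQuery:
    def test_toy_t1_molecule_query(self, toy_t1):
        A = build_adjacency(toy_t1)
        F = diffuse(A, build_transfer_matrix(A))
        table = score_query(toy_t1, F, "s1")
        by_id = {c.candidate_id: c for c in table.candidates}
        assert by_id["m1"].known_link and by_id["m2"].known_link
        assert not by_id["m3"].known_link and by_id["m3"].rank == 1
        assert by_id["m1"].rank == 0 and by_id["m2"].rank == 0

    def test_toy_t1_mirna_query(self, toy_t1):
        A = build_adjacency(toy_t1)
        F = diffuse(A, build_transfer_matrix(A))
        table = score_query(toy_t1, F, "m3")
        by_id = {c.candidate_id: c for c in table.candidates}
        assert by_id["s1"].raw_score == pytest.approx(0.25)
        assert by_id["s2"].raw_score == pytest.approx(0.75)
        assert by_id["s1"].rank == 1  # the only novel candidate

    def test_isolated_query_flagged_unpredictable(self):
        from smirnbi.graph_model import merge_duplicate_edges
        from smirnbi.net_io import Direction, RegulationRecord

        # conflicting pair drops the only edge of "lone"
        records = [
            RegulationRecord("lone", "miR-x", Direction.UP),
            RegulationRecord("lone", "miR-x", Direction.DOWN),
            RegulationRecord("d", "miR-y", Direction.UP),
        ]
        net = merge_duplicate_edges(records)
        A = build_adjacency(net)
        F = diffuse(A, build_transfer_matrix(A))
        table = score_query(net, F, "lone")
        assert table.unpredictable and table.candidates == []

    def test_unknown_query_raises(self, toy_t1):
        A = build_adjacency(toy_t1)
        F = diffuse(A, build_transfer_matrix(A))
        with pytest.raises(KeyError):
            score_query(toy_t1, F, "ghost")

    def test_novel_ranks_are_contiguous_and_tie_broken_lexicographically(self):
        rng = np.random.default_rng(13)
        net = random_bipartite(rng)
        for table in score_all_queries(net, "molecule"):
            if table.unpredictable:
                continue
            novel = sorted((c for c in table.candidates if not c.known_link),
                           key=lambda c: c.rank)
            assert [c.rank for c in novel] == list(range(1, len(novel) + 1))
            for a, b in zip(novel, novel[1:]):
                assert (a.std_score, b.candidate_id) >= (b.std_score, a.candidate_id)


class TestFilterByThreshold:
    def test_toy_t1_novel_candidate_below_threshold_dropped(self, toy_t1):
        tables = score_all_queries(toy_t1, "molecule")
        # s1's only novel candidate m3 standardises to 0.0 < 0.1
        preds = filter_by_threshold(tables, 0.1)
        assert ("s1", "m3", 0.0) not in preds

    def test_zero_threshold_returns_every_novel_candidate(self, toy_t1):
        tables = score_all_queries(toy_t1, "molecule")
        n_novel = sum(1 for t in tables for c in t.candidates if not c.known_link)
        assert len(filter_by_threshold(tables, 0.0)) == n_novel

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_threshold_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError, match="threshold"):
            filter_by_threshold([], bad)
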