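"""TCtriCluster: ratio graph, slice biclusters, temporal merge, pruning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trictl.mining import (
    BiclusterSlice,
    MiningParams,
    Tricluster,
    build_multigraph,
    check_coherence,
    merge_time_contiguous,
    mine_slice_biclusters,
    prune_overlaps,
    ratio_range,
    read_triclusters,
    tc_tricluster,
    write_triclusters,
)

from .conftest import as_key_set, exhaustive_triclusters, numeric_dataset


def mine_slice(values, params, k=0):
    g = build_multigraph(values, np.zeros_like(values, bool), params)
    return mine_slice_biclusters(g, values, params, k)


class TestRatioRange:
    def test_identical_columns_form_one_full_subset(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert ratio_range(v, v, 0.0, 2) == [frozenset({0, 1, 2, 3})]

    def test_exact_scaling_is_coherent_at_epsilon_zero(self):
        a = np.array([1.0, 2.0, 5.0])
        assert ratio_range(a, 2 * a, 0.0, 2) == [frozenset({0, 1, 2})]

    def test_two_ratio_clusters_split(self):
        # ratios 1.00, 1.05, 1.30, 1.32 with eps 0.1 -> {0,1} and {2,3}
        a = np.ones(4)
        b = np.array([1.00, 1.05, 1.30, 1.32])
        assert ratio_range(a, b, 0.1, 2) == [frozenset({0, 1}), frozenset({2, 3})]

    def test_nonpositive_value_is_error(self):
        with pytest.raises(ValueError, match="object 1"):
            ratio_range(np.array([1.0, -2.0]), np.array([1.0, 1.0]), 0.1, 2)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0.5, 10.0), min_size=2, max_size=8),
        st.floats(0.0, 2.0),
    )
    def test_subsets_are_maximal_against_brute_force(self, ratios, eps):
        a = np.ones(len(ratios))
        b = np.array(ratios)
        got = ratio_range(a, b, eps, 1)
        import itertools

        valid = [
            frozenset(S)
            for size in range(1, len(ratios) + 1)
            for S in itertools.combinations(range(len(ratios)), size)
            if max(b[list(S)]) - min(b[list(S)]) <= eps
        ]
        maximal = {S for S in valid if not any(S < T for T in valid)}
        assert set(got) == maximal


class TestSliceBiclusters:
    def test_constant_slice_yields_the_whole_block(self):
        v = np.full((4, 3), 2.0)
        params = MiningParams(epsilon=0.0, mx=2, my=2)
        bics = mine_slice(v, params)
        assert len(bics) == 1
        assert bics[0].object_ids == frozenset(range(4))
        assert bics[0].feature_ids == frozenset(range(3))

    def test_planted_block_recovered_in_noise(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(1, 3, (5, 4))
        v[np.ix_([0, 2, 4], [1, 3])] = 2.0
        params = MiningParams(epsilon=0.01, mx=3, my=2)
        bics = mine_slice(v, params)
        keys = {(tuple(sorted(b.object_ids)), tuple(sorted(b.feature_ids))) for b in bics}
        assert ((0, 2, 4), (1, 3)) in keys

    def test_size_filter_suppresses_small_blocks(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(1, 3, (5, 4))
        v[np.ix_([1, 2], [0, 2])] = 1.5
        params = MiningParams(epsilon=0.01, mx=3, my=2)
        keys = {
            (tuple(sorted(b.object_ids)), tuple(sorted(b.feature_ids)))
            for b in mine_slice(v, params)
        }
        assert ((1, 2), (0, 2)) not in keys

    def test_random_continuous_slice_has_no_edges(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(1, 2, (4, 3))
        params = MiningParams(epsilon=1e-9, mx=2, my=2)
        g = build_multigraph(v, np.zeros_like(v, bool), params)
        assert g.edges == {}


class TestMergeTimeContiguous:
    def b(self, I, J, k):
        return BiclusterSlice(frozenset(I), frozenset(J), k)

    def test_identical_block_across_three_contexts(self):
        blocks = [[self.b({0, 1}, {0, 1}, k)] for k in range(3)]
        params = MiningParams(epsilon=1.0, mx=2, my=2, mz=3)
        tris = merge_time_contiguous(blocks, params)
        assert len(tris) == 1
        assert tris[0].context_ids == (0, 1, 2)

    def test_gap_breaks_contiguity(self):
        blk = self.b({0, 1}, {0, 1}, 0)
        blocks = [[blk], [self.b({0, 1}, {0, 1}, 1)], [], [self.b({0, 1}, {0, 1}, 3)]]
        params3 = MiningParams(epsilon=1.0, mx=2, my=2, mz=3)
        assert merge_time_contiguous(blocks, params3) == []
        params2 = MiningParams(epsilon=1.0, mx=2, my=2, mz=2)
        tris = merge_time_contiguous(blocks, params2)
        assert [t.context_ids for t in tris] == [(0, 1)]

    def test_shrinking_blocks_intersect(self):
        blocks = [
            [self.b({1, 2, 3, 4}, {0, 1}, 0)],
            [self.b({1, 2, 3}, {0, 1}, 1)],
            [self.b({1, 2, 3}, {0, 1}, 2)],
        ]
        params = MiningParams(epsilon=1.0, mx=2, my=2, mz=3)
        tris = merge_time_contiguous(blocks, params)
        assert len(tris) == 1
        assert tris[0].object_ids == (1, 2, 3)
        assert tris[0].context_ids == (0, 1, 2)


class TestPruneOverlaps:
    def test_thresholds_at_one_are_identity(self):
        t1 = Tricluster((0, 1, 2), (0, 1), (0, 1))
        t2 = Tricluster((1, 2, 3), (0, 1), (0, 1))
        params = MiningParams(epsilon=1.0, eta=1.0, gamma=1.0)
        assert prune_overlaps([t1, t2], params) == sorted([t1, t2], key=Tricluster.sort_key)

    def test_contained_tricluster_deleted(self):
        big = Tricluster((0, 1, 2, 3), (0, 1, 2), (0, 1))
        small = Tricluster((0, 1), (0, 1), (0, 1))
        params = MiningParams(epsilon=1.0, eta=0.5)
        assert prune_overlaps([big, small], params) == [big]

    def test_half_overlap_below_eta_keeps_both(self):
        # two 3x2x2 triclusters sharing 6 of their 12 cells
        t1 = Tricluster((0, 1, 2), (0, 1), (0, 1))
        t2 = Tricluster((0, 1, 2), (1, 2), (0, 1))
        assert (
            len(set(t1.cells()) & set(t2.cells())) == 6
        )  # enumerated overlap
        params = MiningParams(epsilon=1.0, eta=0.7, gamma=1.0)
        assert len(prune_overlaps([t1, t2], params)) == 2

    def test_merge_produces_coherent_bounding_block(self):
        v = np.full((4, 3, 2), 2.0)
        ds = numeric_dataset(v)
        t1 = Tricluster((0, 1, 2), (0, 1), (0, 1))
        t2 = Tricluster((1, 2, 3), (0, 1), (0, 1))
        params = MiningParams(epsilon=0.1, mx=2, my=2, mz=2, gamma=0.3)
        out = prune_overlaps([t1, t2], params, data=ds)
        assert out == [Tricluster((0, 1, 2, 3), (0, 1), (0, 1))]


class TestCheckCoherence:
    def test_non_contiguous_context_set_reported(self):
        ds = numeric_dataset(np.full((3, 3, 4), 2.0))
        t = Tricluster((0, 1), (0, 1), (0, 2))
        ok, report = check_coherence(t, ds, MiningParams(epsilon=1.0))
        assert not ok and "contiguity" in report

    def test_perturbed_cell_breaks_coherence(self):
        v = np.full((4, 3, 3), 2.0)
        v[1, 2, 1] += 10
        ds = numeric_dataset(v)
        t = Tricluster((0, 1, 2, 3), (0, 1, 2), (0, 1, 2))
        ok, report = check_coherence(t, ds, MiningParams(epsilon=0.01))
        assert not ok and "ratio range" in report and "context 1" in report

    def test_every_mined_tricluster_passes(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(1, 3, (6, 4, 3))
        v[np.ix_([0, 1, 2], [0, 1], [0, 1, 2])] = 2.0
        ds = numeric_dataset(v)
        params = MiningParams(epsilon=0.05, mx=2, my=2, mz=2)
        for t in tc_tricluster(ds, params):
            ok, report = check_coherence(t, ds, params)
            assert ok, report


class TestTcTricluster:
    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(6):
            v = rng.uniform(1, 3, (6, 4, 3))
            if trial % 2 == 0:
                v[np.ix_([0, 1, 2], [0, 1], [0, 1, 2])] = 2.0
            params = MiningParams(epsilon=0.08 if trial % 3 else 0.4, mx=2, my=2, mz=2)
            assert as_key_set(tc_tricluster(numeric_dataset(v), params)) == (
                exhaustive_triclusters(v, params)
            )

    def test_pure_noise_yields_nothing(self):
        rng = np.random.default_rng(10)
        v = rng.uniform(1, 2, (8, 5, 4))
        params = MiningParams(epsilon=1e-9, mx=2, my=2, mz=2)
        assert tc_tricluster(numeric_dataset(v), params) == []

    def test_deterministic_output_order(self):
        rng = np.random.default_rng(11)
        v = rng.uniform(1, 3, (7, 5, 4))
        v[np.ix_([0, 1, 2, 3], [0, 1, 2], [1, 2, 3])] = 2.0
        ds = numeric_dataset(v)
        params = MiningParams(epsilon=0.05, mx=2, my=2, mz=2)
        assert tc_tricluster(ds, params) == tc_tricluster(ds, params)

    def test_contiguity_invariant(self):
        rng = np.random.default_rng(12)
        v = rng.uniform(1, 3, (8, 5, 5))
        v[np.ix_([0, 1, 2], [0, 1, 2], [0, 1, 2])] = 2.0
        v[np.ix_([4, 5, 6], [2, 3, 4], [2, 3, 4])] = 1.5
        for t in tc_tricluster(numeric_dataset(v), MiningParams(epsilon=0.05, mx=2, my=2, mz=2)):
            ks = t.context_ids
            assert ks == tuple(range(ks[0], ks[-1] + 1))

    def test_expansion_breaks_coherence(self):
        """Maximality: no single-object/feature/adjacent-context extension stays coherent."""
        rng = np.random.default_rng(13)
        v = rng.uniform(1, 3, (6, 4, 4))
        v[np.ix_([0, 1, 2], [0, 1], [0, 1, 2])] = 2.0
        ds = numeric_dataset(v)
        params = MiningParams(epsilon=0.05, mx=2, my=2, mz=2)
        for t in tc_tricluster(ds, params):
            for i in set(range(6)) - set(t.object_ids):
                grown = Tricluster(t.object_ids + (i,), t.feature_ids, t.context_ids)
                assert not check_coherence(grown, ds, params)[0]
            for j in set(range(4)) - set(t.feature_ids):
                grown = Tricluster(t.object_ids, t.feature_ids + (j,), t.context_ids)
                assert not check_coherence(grown, ds, params)[0]
            for k in (t.context_ids[0] - 1, t.context_ids[-1] + 1):
                if 0 <= k < 4:
                    grown = Tricluster(t.object_ids, t.feature_ids, t.context_ids + (k,))
                    assert not check_coherence(grown, ds, params)[0]

    def test_epsilon_monotonicity_of_covered_cells(self):
        rng = np.random.default_rng(14)
        v = rng.uniform(1, 3, (6, 4, 3))
        v[np.ix_([0, 1, 2], [0, 1], [0, 1, 2])] = 2.0
        ds = numeric_dataset(v)

        def covered(eps):
            cells = set()
            for t in tc_tricluster(ds, MiningParams(epsilon=eps, mx=2, my=2, mz=2)):
                cells |= t.cells()
            return cells

        assert covered(0.02) <= covered(0.1) <= covered(0.5)

    def test_missing_cells_are_skipped_not_imputed(self):
        v = np.full((4, 3, 3), 2.0)
        mask = np.zeros_like(v, bool)
        mask[3, :, :] = True  # object 3 unobserved everywhere
        ds = numeric_dataset(v, mask)
        params = MiningParams(epsilon=0.01, mx=2, my=2, mz=2)
        tris = tc_tricluster(ds, params)
        assert len(tris) == 1
        assert tris[0].object_ids == (0, 1, 2)

    def test_shift_makes_zero_scores_minable(self):
        v = np.zeros((3, 2, 2))
        ds = numeric_dataset(v)
        with pytest.raises(ValueError, match="non-positive"):
            tc_tricluster(ds, MiningParams(epsilon=0.01, mx=2, my=2, mz=2))
        tris = tc_tricluster(ds, MiningParams(epsilon=0.01, mx=2, my=2, mz=2, shift=1.0))
        assert len(tris) == 1

    def test_jsonl_round_trip(self, tmp_path):
        tris = [Tricluster((0, 1), (0, 2), (1, 2)), Tricluster((2, 3), (1, 2), (0, 1))]
        path = tmp_path / "t.jsonl"
        write_triclusters(tris, path, MiningParams(epsilon=0.1))
        assert read_triclusters(path) == tris
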