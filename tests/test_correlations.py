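"""Pairwise correlations, surrogate significance, clustering, reordering."""

import numpy as np
import pytest

from crackling import (
    CorrelationMatrix,
    SpikeRaster,
    cluster_order,
    correlation_significance,
    pairwise_correlation,
    reorder_by_reference,
)
from crackling.exceptions import ParameterError


def _raster(values, bin_width=0.25, ids=None):
    return SpikeRaster(np.asarray(values, dtype=np.uint8), bin_width, ids or [])


class TestPairwiseCorrelation:
    def test_identical_trains_correlate_at_one(self):
        row = (np.random.default_rng(0).random(500) < 0.3).astype(np.uint8)
        matrix = pairwise_correlation(_raster([row, row]))
        assert matrix.values[0, 1] == pytest.approx(1.0)

    def test_complementary_trains_correlate_at_minus_one(self):
        row = (np.random.default_rng(1).random(500) < 0.5).astype(np.uint8)
        matrix = pairwise_correlation(_raster([row, 1 - row]))
        assert matrix.values[0, 1] == pytest.approx(-1.0)

    def test_independent_trains_have_near_zero_coefficients(self):
        T = 10_000
        rng = np.random.default_rng(2)
        values = (rng.random((10, T)) < 0.2).astype(np.uint8)
        matrix = pairwise_correlation(_raster(values))
        off = matrix.offdiagonal()
        assert np.abs(off).mean() < 3 / np.sqrt(T)

    def test_constant_train_is_flagged_undefined_not_zeroed(self):
        rng = np.random.default_rng(3)
        values = np.vstack([(rng.random(200) < 0.3), np.zeros(200)]).astype(np.uint8)
        matrix = pairwise_correlation(_raster(values))
        assert np.isnan(matrix.values[0, 1])
        assert not matrix.defined[0, 1]

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(4)
        values = (rng.random((6, 400)) < 0.2).astype(np.uint8)
        matrix = pairwise_correlation(_raster(values))
        assert np.allclose(matrix.values, matrix.values.T, atol=1e-12)
        assert np.allclose(np.diag(matrix.values), 1.0)

    def test_single_neuron_rejected(self):
        with pytest.raises(ParameterError):
            pairwise_correlation(_raster(np.zeros((1, 10))))


class TestSignificance:
    def test_identical_trains_are_significant(self):
        row = (np.random.default_rng(5).random(1000) < 0.2).astype(np.uint8)
        raster = _raster([row, row])
        matrix = pairwise_correlation(raster)
        sig = correlation_significance(matrix, raster, n_surrogates=200, seed=6)
        assert sig[0, 1]

    def test_zero_rate_neuron_is_untestable(self):
        rng = np.random.default_rng(7)
        values = np.vstack([(rng.random(300) < 0.3), (rng.random(300) < 0.3),
                            np.zeros(300)]).astype(np.uint8)
        raster = _raster(values)
        matrix = pairwise_correlation(raster)
        sig = correlation_significance(matrix, raster, n_surrogates=200, seed=8)
        assert not sig[0, 2] and not sig[1, 2]
        assert np.isnan(matrix.p_values[0, 2])

    def test_flagged_fraction_calibrates_to_p_threshold(self):
        rng = np.random.default_rng(9)
        values = (rng.random((30, 4000)) < 0.05).astype(np.uint8)
        raster = _raster(values)
        matrix = pairwise_correlation(raster)
        sig = correlation_significance(matrix, raster, n_surrogates=1000,
                                       p_threshold=0.1, seed=10)
        frac = sig[np.triu_indices(30, 1)].mean()
        assert frac == pytest.approx(0.1, abs=0.03)


class TestClustering:
    def _two_block_matrix(self, n=10):
        rng = np.random.default_rng(11)
        r = np.zeros((n, n))
        half = n // 2
        block = np.zeros(n, dtype=bool)
        block[:half] = True
        for i in range(n):
            for j in range(n):
                r[i, j] = 0.8 if block[i] == block[j] else 0.0
        np.fill_diagonal(r, 1.0)
        perm = rng.permutation(n)
        return CorrelationMatrix(r[np.ix_(perm, perm)], [f"n{i}" for i in perm]), perm, half

    def test_two_block_structure_comes_out_contiguous(self):
        matrix, perm, half = self._two_block_matrix()
        order = cluster_order(matrix)
        labels = [int(matrix.neuron_ids[i][1:]) < half for i in order]
        # each block occupies one contiguous stretch of the leaf order
        assert sum(a != b for a, b in zip(labels, labels[1:])) == 1

    def test_equivariance_under_input_permutation(self):
        matrix, _, _ = self._two_block_matrix()
        order = cluster_order(matrix)
        grouping = [matrix.neuron_ids[i] for i in order]
        rng = np.random.default_rng(12)
        perm = rng.permutation(matrix.n_neurons)
        permuted = CorrelationMatrix(
            matrix.values[np.ix_(perm, perm)], [matrix.neuron_ids[i] for i in perm])
        grouping2 = [permuted.neuron_ids[i] for i in cluster_order(permuted)]
        # same partition into contiguous blocks (leaf order may flip)
        half = len(grouping) // 2
        assert {frozenset(grouping[:half]), frozenset(grouping[half:])} == \
               {frozenset(grouping2[:half]), frozenset(grouping2[half:])}

    def test_undefined_neurons_are_appended_last(self):
        matrix, _, _ = self._two_block_matrix()
        matrix.values[3, :] = np.nan
        matrix.values[:, 3] = np.nan
        order = cluster_order(matrix)
        assert order[-1] == 3

    def test_fewer_than_two_clusterable_returns_identity(self):
        values = np.full((3, 3), np.nan)
        matrix = CorrelationMatrix(values, ["a", "b", "c"])
        assert cluster_order(matrix).tolist() == [0, 1, 2]


class TestReorderByReference:
    def test_identity_reference_is_unchanged(self):
        rng = np.random.default_rng(13)
        raster = _raster((rng.random((4, 300)) < 0.3).astype(np.uint8))
        matrix = pairwise_correlation(raster)
        out = reorder_by_reference(matrix, matrix.neuron_ids)
        assert np.allclose(out.values, matrix.values)

    def test_missing_neurons_become_blank_rows(self):
        rng = np.random.default_rng(14)
        raster = _raster((rng.random((3, 300)) < 0.3).astype(np.uint8), ids=["a", "b", "c"])
        matrix = pairwise_correlation(raster)
        out = reorder_by_reference(matrix, ["c", "x", "a", "b"])
        assert np.isnan(out.values[1, :]).all() and np.isnan(out.values[:, 1]).all()
        assert out.values[0, 2] == pytest.approx(matrix.values[2, 0])

    def test_offdiagonal_multiset_invariant_under_reordering(self):
        rng = np.random.default_rng(15)
        raster = _raster((rng.random((6, 500)) < 0.2).astype(np.uint8))
        matrix = pairwise_correlation(raster)
        shuffled_ids = list(matrix.neuron_ids)
        rng.shuffle(shuffled_ids)
        out = reorder_by_reference(matrix, shuffled_ids)
        assert np.allclose(np.sort(out.offdiagonal()), np.sort(matrix.offdiagonal()))

    def test_reorganized_condition_loses_block_structure_under_reference_order(self):
        # two conditions with different ground-truth group structure: under
        # the reference (grating-like) ordering, the other condition's
        # within-block correlation drops
        rng = np.random.default_rng(16)
        T, n = 4000, 12
        drive_a = (rng.random(T) < 0.15).astype(np.uint8)
        drive_b = (rng.random(T) < 0.15).astype(np.uint8)
        noise = lambda: (rng.random(T) < 0.05).astype(np.uint8)
        # condition 1: neurons 0-5 follow drive_a, 6-11 follow drive_b
        cond1 = np.array([np.maximum(drive_a if i < 6 else drive_b, noise()) for i in range(n)])
        # condition 2: alternating membership (different grouping)
        cond2 = np.array([np.maximum(drive_a if i % 2 else drive_b, noise()) for i in range(n)])
        m1 = pairwise_correlation(_raster(cond1))
        m2 = pairwise_correlation(_raster(cond2))
        order = cluster_order(m1)
        ref_ids = [m1.neuron_ids[i] for i in order]
        r1 = reorder_by_reference(m1, ref_ids).values
        r2 = reorder_by_reference(m2, ref_ids).values
        within = np.zeros((n, n), dtype=bool)
        within[:6, :6] = within[6:, 6:] = True
        within &= ~np.eye(n, dtype=bool)
        assert np.nanmean(r1[within]) > np.nanmean(r2[within])
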