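import numpy as np
import pytest

from freqclust import ROIMatrix, detrend_linear, drop_initial_volumes, extract_roi_series, zscore
from freqclust.preprocess import preprocess_matrix


def make_matrix(n_rois=3, n_t=225, fs=0.5, seed=0):
    rng = np.random.default_rng(seed)
    return ROIMatrix(rng.standard_normal((n_rois, n_t)), fs=fs,
                     roi_ids=list(range(1, n_rois + 1)))


class TestDropInitialVolumes:
    @pytest.mark.parametrize("n_t,n_drop,expected", [(225, 5, 220), (145, 5, 140)])
    def test_dummy_scan_removal(self, n_t, n_drop, expected):
        mat = make_matrix(n_t=n_t)
        out = drop_initial_volumes(mat, n_drop)
        assert out.n_timepoints == expected
        assert np.array_equal(out.data, mat.data[:, n_drop:])

    def test_zero_drop_is_identity(self):
        mat = make_matrix()
        out = drop_initial_volumes(mat, 0)
        assert np.array_equal(out.data, mat.data)

    def test_dropping_everything_rejected(self):
        with pytest.raises(ValueError):
            drop_initial_volumes(make_matrix(n_t=10), 10)

    def test_works_on_4d_volume(self):
        vol = np.random.default_rng(0).standard_normal((4, 4, 3, 20))
        out = drop_initial_volumes(vol, 5)
        assert out.shape == (4, 4, 3, 15)
        assert np.array_equal(out, vol[..., 5:])


class TestDetrendLinear:
    def test_pure_trend_removed(self):
        t = np.arange(100, dtype=float)
        out = detrend_linear(2 + 0.3 * t)
        assert np.max(np.abs(out)) < 1e-10

    def test_trendfree_input_unchanged(self):
        t = np.arange(200, dtype=float)
        x = np.sin(2 * np.pi * t / 20)
        x = detrend_linear(x)
        assert np.allclose(detrend_linear(x), x, atol=1e-10)

    def test_orthogonal_to_constant_and_ramp(self):
        rng = np.random.default_rng(3)
        out = detrend_linear(rng.standard_normal(150))
        t = np.arange(150, dtype=float)
        assert abs(out.sum()) < 1e-8
        assert abs((out * (t - t.mean())).sum()) < 1e-6

    def test_recovers_sinusoid_under_drift(self):
        # oracle: direct least-squares fit of [1, t] removed by hand
        fs, n = 0.5, 220
        t = np.arange(n) / fs
        sin_part = np.sin(2 * np.pi * 0.05 * t)
        x = sin_part + 0.1 * t
        A = np.vstack([np.ones(n), t]).T
        expected = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
        out = detrend_linear(x)
        assert np.allclose(out, expected, atol=1e-8)
        assert np.corrcoef(out, sin_part)[0, 1] > 0.99

    def test_constant_input_gives_zeros(self):
        assert np.allclose(detrend_linear(np.full(50, 3.7)), 0, atol=1e-10)


class TestZscore:
    def test_definition(self):
        out = zscore(np.array([1.0, 2.0, 3.0]))
        assert out.mean() == pytest.approx(0, abs=1e-12)
        assert out.std() == pytest.approx(1, abs=1e-12)

    def test_idempotent(self, rng):
        x = rng.standard_normal(100)
        assert np.allclose(zscore(zscore(x)), zscore(x), atol=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(100)
        assert np.allclose(zscore(3.2 * x + 7), zscore(x), atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            zscore(np.ones(20))


class TestExtractRoiSeries:
    def test_mean_of_two_voxels(self):
        rng = np.random.default_rng(1)
        vol = np.zeros((2, 1, 1, 30))
        u, v = rng.standard_normal(30), rng.standard_normal(30)
        vol[0, 0, 0], vol[1, 0, 0] = u, v
        atlas = np.ones((2, 1, 1), dtype=int)
        out = extract_roi_series(vol, atlas, [1])
        assert np.allclose(out.data[0], (u + v) / 2)

    def test_single_voxel_roi_identity(self):
        vol = np.zeros((2, 1, 1, 10))
        vol[0, 0, 0] = np.arange(10)
        atlas = np.array([[[1]], [[2]]])
        out = extract_roi_series(vol, atlas, [1])
        assert np.array_equal(out.data[0], np.arange(10))

    def test_identical_voxel_series_returned_exactly(self):
        # power-of-two voxel count keeps the mean of equal values exact
        series = np.sin(np.arange(25) / 3)
        vol = np.broadcast_to(series, (2, 2, 1, 25)).copy()
        atlas = np.ones((2, 2, 1), dtype=int)
        out = extract_roi_series(vol, atlas, [1])
        assert np.array_equal(out.data[0], series)

    def test_missing_label_named_in_error(self):
        vol = np.zeros((2, 2, 2, 5))
        atlas = np.ones((2, 2, 2), dtype=int)
        with pytest.raises(ValueError, match="99"):
            extract_roi_series(vol, atlas, [99])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            extract_roi_series(np.zeros((2, 2, 2, 5)), np.ones((3, 2, 2), dtype=int), [1])

    def test_negative_labels_rejected(self):
        atlas = -np.ones((2, 2, 2), dtype=int)
        with pytest.raises(ValueError):
            extract_roi_series(np.zeros((2, 2, 2, 5)), atlas, [1])

    def test_permutation_equivariant_in_roi_ids(self):
        rng = np.random.default_rng(2)
        vol = rng.standard_normal((4, 4, 4, 12))
        atlas = rng.integers(1, 4, size=(4, 4, 4))
        a = extract_roi_series(vol, atlas, [1, 2, 3])
        b = extract_roi_series(vol, atlas, [3, 1, 2])
        assert np.allclose(a.data[[2, 0, 1]], b.data)


class TestPipelineOrder:
    def test_preprocessed_rows_are_zero_mean_unit_sd_trendfree(self):
        mat = make_matrix(n_rois=4, n_t=225, seed=5)
        mat.data += np.linspace(0, 3, 225)  # common drift
        out = preprocess_matrix(mat, n_drop=5)
        assert out.n_timepoints == 220
        t = np.arange(220, dtype=float)
        for row in out.data:
            assert row.mean() == pytest.approx(0, abs=1e-10)
            assert row.std() == pytest.approx(1, abs=1e-10)
            assert abs((row * (t - t.mean())).sum()) < 1e-6

    def test_constant_roi_identified_in_error(self):
        mat = make_matrix(n_rois=2, n_t=50)
        mat.data[1] = 4.2
        with pytest.raises(ValueError, match="2"):
            preprocess_matrix(mat)
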