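"""Group inference: voxelwise tests, smoothness, cluster thresholding, Bayes."""

import numpy as np
import pytest
from scipy import ndimage, stats

from plastimap import inference
from plastimap.maps import StatMap, ellipsoid_mask


def _maps(n, shape=(10, 10, 10), seed=0, offset=0.0, group="A", subjects=None):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        data = rng.standard_normal(shape) + offset
        out.append(StatMap(data, "contrast", subject=subjects[i] if subjects
                           else f"{group}{i}", group=group))
    return out


class TestVoxelwiseTest:
    def test_identical_paired_sets_give_zero_t(self):
        a = _maps(5, seed=1, subjects=[f"s{i}" for i in range(5)])
        b = [m.with_data(m.data) for m in a]
        t = inference.voxelwise_test(a, b, design="paired")
        vals = t.data[np.isfinite(t.data)]
        np.testing.assert_allclose(vals, 0.0)

    def test_label_swap_negates_t(self):
        a, b = _maps(6, seed=2), _maps(6, seed=3, offset=0.5)
        t_ab = inference.voxelwise_test(a, b)
        t_ba = inference.voxelwise_test(b, a)
        np.testing.assert_allclose(t_ab.data, -t_ba.data, atol=1e-12)

    def test_null_exceedance_near_height_alpha(self):
        a, b = _maps(15, seed=4), _maps(15, seed=5)
        t = inference.voxelwise_test(a, b)
        thr = stats.t.ppf(0.99, t.df)
        frac = np.mean(t.data > thr)
        se = np.sqrt(0.01 * 0.99 / t.data.size)
        assert abs(frac - 0.01) < 4 * se

    def test_paired_subject_mismatch_rejected(self):
        a = _maps(4, subjects=["s1", "s2", "s3", "s4"])
        b = _maps(4, subjects=["s1", "s2", "s4", "s3"])
        with pytest.raises(ValueError, match="matched subjects"):
            inference.voxelwise_test(a, b, design="paired")

    def test_collinear_covariate_rejected(self):
        a, b = _maps(5, seed=6), _maps(5, seed=7)
        cov = np.concatenate([np.ones(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            inference.voxelwise_test(a, b, covariate=cov)

    def test_covariate_control_keeps_group_effect(self):
        rng = np.random.default_rng(8)
        a = _maps(15, seed=8, offset=1.0)
        b = _maps(15, seed=9)
        cov = rng.standard_normal(30)
        t_cov = inference.voxelwise_test(a, b, covariate=cov)
        assert t_cov.df == 27
        assert np.nanmean(t_cov.data) > 1.0


class TestSmoothness:
    def test_white_noise_close_to_voxel_size(self):
        rng = np.random.default_rng(0)
        resid = [rng.standard_normal((16, 16, 16)) for _ in range(10)]
        fwhm = inference.estimate_smoothness(resid, np.ones((16, 16, 16), bool),
                                             voxel_size=2.0)
        # gradient-variance estimator gives ~1.18 voxels for white noise:
        # FWHM = dx * sqrt(4 ln 2) / sqrt(var(diff)) with var(diff) = 2
        np.testing.assert_allclose(fwhm, 2.0 * np.sqrt(4 * np.log(2) / 2), rtol=0.05)

    def test_recovers_6mm_kernel_within_15_percent(self):
        rng = np.random.default_rng(1)
        sigma = 6.0 / 2.3548 / 2.0
        resid = [ndimage.gaussian_filter(rng.standard_normal((20, 20, 20)), sigma)
                 for _ in range(10)]
        fwhm = inference.estimate_smoothness(resid, np.ones((20, 20, 20), bool),
                                             voxel_size=2.0)
        assert np.all(np.abs(fwhm - 6.0) / 6.0 < 0.15)

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            inference.estimate_smoothness([np.ones((10, 10, 10))] * 3,
                                          np.ones((10, 10, 10), bool))

    def test_small_mask_rejected(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[:3, :3, :3] = True
        with pytest.raises(ValueError, match="mask too small"):
            inference.estimate_smoothness([np.zeros((10, 10, 10))] * 2, mask)


class TestClusterExtentThreshold:
    def test_alpha_one_gives_kmin_one(self):
        mask = np.ones((8, 8, 8), bool)
        k = inference.cluster_extent_threshold(mask, 0.0, height_p=0.01,
                                               alpha=1.0, n_sim=1000, seed=0)
        assert k == 1

    def test_monotone_in_smoothness(self):
        mask = ellipsoid_mask((14, 14, 14))
        k0 = inference.cluster_extent_threshold(mask, 0.0, n_sim=1500, seed=1)
        k6 = inference.cluster_extent_threshold(mask, 6.0, n_sim=1500, seed=1)
        assert k6 >= k0

    def test_reproducible_under_seed(self):
        mask = np.ones((10, 10, 10), bool)
        a = inference.cluster_extent_threshold(mask, 4.0, n_sim=1000, seed=3)
        b = inference.cluster_extent_threshold(mask, 4.0, n_sim=1000, seed=3)
        assert a == b

    def test_unreachable_alpha_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            inference.cluster_extent_threshold(np.ones((8, 8, 8), bool), 0.0,
                                               alpha=1e-5, n_sim=1000, seed=0)


class TestExtractClusters:
    def _tmap(self, data, df=28):
        return StatMap(data, "t", df=df)

    def test_empty_when_nothing_suprathreshold(self):
        table = inference.extract_clusters(self._tmap(np.zeros((8, 8, 8))))
        assert table.clusters.empty

    def test_large_blob_survives_extent(self):
        data = np.zeros((12, 12, 12))
        data[2:10, 2:10, 2:6] = 10.0       # 256 voxels
        table = inference.extract_clusters(self._tmap(data), k_min=128)
        assert len(table.surviving) == 1
        assert table.surviving["size"].iloc[0] == 256

    def test_corner_touching_blobs_connectivity(self):
        data = np.zeros((10, 10, 10))
        data[2:4, 2:4, 2:4] = 10.0
        data[4:6, 4:6, 4:6] = 10.0          # shares only the corner at (4,4,4)
        t = self._tmap(data)
        t26 = inference.extract_clusters(t, connectivity=26)
        t6 = inference.extract_clusters(t, connectivity=6)
        assert len(t26.clusters) == 1
        assert len(t6.clusters) == 2

    def test_directions_separated(self):
        data = np.zeros((10, 10, 10))
        data[2:4, 2:4, 2:4] = 8.0
        data[6:8, 6:8, 6:8] = -8.0
        table = inference.extract_clusters(self._tmap(data))
        assert set(table.clusters["direction"]) == {"A>B", "B>A"}


class TestHdi:
    def test_matches_quantiles_for_symmetric_sample(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100_000)
        lo, hi = inference.hdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)


class TestBayesGroupDiff:
    def test_identical_groups_centre_on_zero(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(15)
        s = inference.bayes_group_diff(a, a.copy(), seed=1)
        assert abs(s.mean_diff) < 0.5
        assert s.hdi_contains_zero()

    def test_separated_groups_exclude_zero(self):
        rng = np.random.default_rng(1)
        s = inference.bayes_group_diff(rng.standard_normal(15) + 3.0,
                                       rng.standard_normal(15), seed=2)
        assert not s.hdi_contains_zero()
        assert s.mean_diff == pytest.approx(3.0, abs=1.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            inference.bayes_group_diff(np.ones(2), np.ones(5), seed=0)
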