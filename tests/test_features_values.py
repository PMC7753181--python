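"""Feature formula values: intensity statistics, worked texture examples,
normalization invariants, and the named signature-model features."""

import numpy as np
import pytest

from radiomap.features.intensity import intensity_features
from radiomap.features.matrices import texture_matrices
from radiomap.features.texture import (
    glcm_features,
    glrlm_features,
    glszm_features,
    ngldm_features,
    ngtdm_features,
)


class TestIntensity:
    def test_constant_values(self):
        f = intensity_features(np.full(3, -100.0),
                               ("median", "percentile_90", "variance", "mean"))
        assert f["median"] == -100 and f["percentile_90"] == -100 and f["variance"] == 0

    def test_linear_interpolated_percentiles(self):
        f = intensity_features(np.arange(1, 101, dtype=float), ("median", "percentile_90"))
        assert f["median"] == pytest.approx(50.5)
        assert f["percentile_90"] == pytest.approx(90.1)

    def test_energy_is_sum_of_squares(self):
        f = intensity_features(np.array([1.0, 2.0, 2.0]), ("energy",))
        assert f["energy"] == 9.0

    def test_single_voxel_dispersion_is_sentinel(self):
        f = intensity_features(np.array([5.0]), ("mean", "variance", "skewness", "range"))
        assert f["mean"] == 5.0
        assert np.isnan(f["variance"]) and np.isnan(f["skewness"]) and np.isnan(f["range"])

    def test_matches_numpy_moments(self, rng):
        x = rng.normal(-300, 120, 500)
        f = intensity_features(x, ("mean", "variance", "skewness", "interquartile_range"))
        assert f["mean"] == pytest.approx(x.mean())
        assert f["variance"] == pytest.approx(x.var())
        assert f["interquartile_range"] == pytest.approx(
            np.percentile(x, 75) - np.percentile(x, 25)
        )


class TestGLCMValues:
    def test_strip_contrast_and_correlation(self):
        # bins [0,1,0,1]: merged GLCM has p(0,1)=p(1,0)=1/2 -> contrast 1,
        # marginal variance 1/4 > 0 so correlation is defined and equals -1
        bins = np.array([0, 1, 0, 1]).reshape(4, 1, 1)
        mats = texture_matrices(bins)
        f = glcm_features(mats.glcm_merged, mats.n_levels)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["correlation"] == pytest.approx(-1.0)

    def test_single_level_contrast_zero_correlation_sentinel(self):
        mats = texture_matrices(np.zeros((3, 3, 3), dtype=int))
        f = glcm_features(mats.glcm_merged, mats.n_levels)
        assert f["contrast"] == 0.0
        assert np.isnan(f["correlation"])

    def test_normalized_form_sums_to_one(self, rng):
        bins = rng.integers(0, 5, (5, 5, 5))
        mats = texture_matrices(bins)
        p = mats.glcm_merged / mats.glcm_merged.sum()
        assert p.sum() == pytest.approx(1.0, abs=1e-9)


class TestGLSZMValues:
    def test_three_equal_zones_fixture(self):
        # three 26-connected zones, each of size 3
        bins = np.array([[0, 0, 1], [0, 1, 1], [2, 2, 2]]).reshape(3, 3, 1)
        mats = texture_matrices(bins)
        f = glszm_features(mats.glszm, mats.n_voxels)
        # all zones share one size -> the zone-size distribution is maximally
        # concentrated; one zone per grey level -> grey levels are uniform
        assert f["zone_size_nonuniformity_norm"] == pytest.approx(1.0)
        assert f["grey_level_nonuniformity_norm"] == pytest.approx(1.0 / 3.0)
        assert f["zone_percentage"] == pytest.approx(3.0 / 9.0)

    def test_single_zone_roi(self):
        mats = texture_matrices(np.zeros((2, 2, 2), dtype=int))
        f = glszm_features(mats.glszm, mats.n_voxels)
        assert f["zone_size_nonuniformity_norm"] == pytest.approx(1.0)

    def test_every_voxel_its_own_zone_gives_percentage_one(self):
        # 3D checkerboard-like pattern where no two equal bins touch
        bins = np.arange(8).reshape(2, 2, 2)
        mats = texture_matrices(bins)
        f = glszm_features(mats.glszm, mats.n_voxels)
        assert f["zone_percentage"] == pytest.approx(1.0)

    def test_zsnn_in_unit_interval(self, rng):
        for _ in range(5):
            bins = rng.integers(0, 4, (4, 4, 4))
            mats = texture_matrices(bins)
            v = glszm_features(mats.glszm, mats.n_voxels)["zone_size_nonuniformity_norm"]
            assert 0.0 < v <= 1.0


class TestDirectFormulaOracles:
    """The ten signature-model features recomputed by direct formula evaluation."""

    def test_table_features_match_direct_evaluation(self, rng):
        bins = rng.integers(0, 4, (5, 5, 4))
        mats = texture_matrices(bins, alphas=(0,))
        n_levels = mats.n_levels

        # GLCM merged
        P = mats.glcm_merged / mats.glcm_merged.sum()
        i = np.arange(1, n_levels + 1, dtype=float)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        f = glcm_features(mats.glcm_merged, n_levels)
        assert f["contrast"] == pytest.approx(((ii - jj) ** 2 * P).sum())
        off = ii != jj
        assert f["inverse_variance"] == pytest.approx((P[off] / (ii - jj)[off] ** 2).sum())
        mu = (ii * P).sum()
        sig2 = (((ii - mu) ** 2) * P).sum()
        assert f["correlation"] == pytest.approx(((ii * jj * P).sum() - mu**2) / sig2)
        assert f["inverse_difference_normalized"] == pytest.approx(
            (P / (1 + np.abs(ii - jj) / n_levels)).sum()
        )

        # GLRLM merged: run entropy
        R = mats.glrlm_merged
        p = R / R.sum()
        p = p[p > 0]
        assert glrlm_features(R, mats.n_voxels)["run_entropy"] == pytest.approx(
            -(p * np.log2(p)).sum()
        )

        # GLSZM: ZSNN and zone percentage
        Z = mats.glszm
        nz = Z.sum()
        col = Z.sum(axis=0).astype(float)
        fz = glszm_features(Z, mats.n_voxels)
        assert fz["zone_size_nonuniformity_norm"] == pytest.approx((col**2).sum() / nz**2)
        assert fz["zone_percentage"] == pytest.approx(nz / mats.n_voxels)

        # NGLDM: low dependence emphasis
        D = mats.ngldm_by_alpha[0]
        d = D.sum(axis=0) / D.sum()
        k = np.arange(1, 28, dtype=float)
        assert ngldm_features(D, mats.n_voxels)["low_dependence_emphasis"] == pytest.approx(
            (d / k**2).sum()
        )

    def test_run_entropy_nonnegative_and_zero_iff_single_run(self, rng):
        mats = texture_matrices(rng.integers(0, 3, (4, 4, 4)))
        assert glrlm_features(mats.glrlm_merged, mats.n_voxels)["run_entropy"] >= 0
        const = texture_matrices(np.zeros((1, 1, 3), dtype=int))
        # a 3-voxel line of one level: each direction gives one run
        f = glrlm_features(const.glrlm_merged, const.n_voxels)
        assert f["run_entropy"] >= 0


def test_ngtdm_uniform_field_has_nan_coarseness_and_zero_sum():
    mats = texture_matrices(np.zeros((3, 3, 3), dtype=int))
    f = ngtdm_features(mats.ngtdm_s, mats.ngtdm_n)
    assert np.isnan(f["coarseness"])  # 1/0 -> sentinel
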