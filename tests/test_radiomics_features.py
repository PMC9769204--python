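"""Resampling, discretization, conventional metrics and feature formulas."""

import numpy as np
import pytest

from petrad.imaging import SUV, VoiMask, Volume
from petrad.radiomics import (
    FEATURE_NAMES,
    DiscretizationConfig,
    ResampleConfig,
    TextureMatrices,
    build_texture_matrices,
    conventional_features,
    discretize,
    extract_all,
    glcm_features,
    glrlm_features,
    glzlm_features,
    histogram_features,
    resample_isotropic,
    shape_features,
    suv_peak,
)
from petrad.radiomics.discretize import DiscretizedVOI
from petrad.synthetic import PhantomSpec, make_phantom

from conftest import uniform_voi_volume
from oracles import brute_suv_peak


def _vol(data, spacing=(4.0, 4.0, 4.0)):
    return Volume(data=np.asarray(data, float), spacing=spacing, units=SUV)


def _full_voi(shape, spacing=(4.0, 4.0, 4.0)):
    return VoiMask(mask=np.ones(shape, dtype=bool), spacing=spacing)


class TestDiscretize:
    @pytest.mark.parametrize(
        "suv,level", [(1.0, 5), (0.0, 1), (0.249999, 1), (0.25, 2), (7.9, 32)]
    )
    def test_bin_assignment(self, suv, level):
        vol = _vol(np.full((2, 2, 2), suv))
        d = discretize(vol, _full_voi((2, 2, 2)))
        assert d.voi_levels[0] == level

    def test_uniform_voi_single_level(self):
        vol, voi = uniform_voi_volume(8.0)
        d = discretize(vol, voi)
        assert d.n_levels == 33  # floor(8/0.25)+1
        assert np.unique(d.voi_levels).size == 1

    def test_below_lower_bound_rejected(self):
        vol = _vol(np.full((2, 2, 2), 0.5))
        cfg = DiscretizationConfig(lower_bound=1.0)
        with pytest.raises(ValueError, match="lower bound"):
            discretize(vol, _full_voi((2, 2, 2)), cfg)


class TestResample:
    def test_noop_on_target_grid(self, rng):
        data = rng.random((6, 6, 6))
        vol = _vol(data)
        voi = VoiMask(mask=rng.random((6, 6, 6)) < 0.5, spacing=(4, 4, 4))
        voi.mask[3, 3, 3] = True
        rv, rm = resample_isotropic(vol, voi, ResampleConfig((4, 4, 4)))
        np.testing.assert_array_equal(rv.data, data)
        np.testing.assert_array_equal(rm.mask, voi.mask)

    def test_constant_stays_constant(self):
        vol = _vol(np.full((5, 5, 5), 3.3), spacing=(4.07, 4.07, 5.0))
        voi = VoiMask(mask=np.ones((5, 5, 5), bool), spacing=(4.07, 4.07, 5.0))
        rv, _ = resample_isotropic(vol, voi)
        np.testing.assert_allclose(rv.data, 3.3, rtol=1e-12)

    def test_linear_ramp_exact_at_half_spacing(self):
        """Trilinear interpolation reproduces affine fields exactly."""
        x = np.arange(8, dtype=float)
        data = np.broadcast_to(x[:, None, None], (8, 6, 6)).copy()
        vol = _vol(data, spacing=(4, 4, 4))
        voi = _full_voi((8, 6, 6))
        rv, _ = resample_isotropic(vol, voi, ResampleConfig((2, 2, 2)))
        expected = np.arange(rv.shape[0]) * 0.5
        interior = slice(0, 15)  # stays inside the original grid support
        np.testing.assert_allclose(rv.data[interior, 4, 4], expected[interior], atol=1e-9)

    def test_empty_mask_rejected(self):
        vol = _vol(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="empty VOI"):
            resample_isotropic(vol, VoiMask(mask=np.zeros((4, 4, 4), bool), spacing=(4, 4, 4)))


class TestConventional:
    def test_uniform_lesion_closed_form(self):
        data = np.full((10, 10, 10), 8.0)
        mask = np.zeros((10, 10, 10), bool)
        mask[3:7, 3:8, 3:8] = True  # 100 voxels
        feats = conventional_features(_vol(data), VoiMask(mask=mask, spacing=(4, 4, 4)))
        assert feats["SUVmax"] == feats["SUVmean"] == feats["SUVpeak"] == 8.0
        assert feats["MTV"] == pytest.approx(6.4)
        assert feats["TLG"] == pytest.approx(51.2)

    def test_tlg_identity_random(self, rng):
        data = rng.random((12, 12, 12)) * 15
        mask = rng.random((12, 12, 12)) < 0.3
        mask[6, 6, 6] = True
        voi = VoiMask(mask=mask, spacing=(4.07, 4.07, 5.0))
        feats = conventional_features(_vol(data, (4.07, 4.07, 5.0)), voi)
        assert feats["TLG"] == feats["SUVmean"] * feats["MTV"]  # machine precision

    def test_peak_below_max_for_hot_voxel(self):
        data = np.full((11, 11, 11), 2.0)
        data[5, 5, 5] = 20.0
        voi = VoiMask(mask=np.ones((11, 11, 11), bool), spacing=(4, 4, 4))
        feats = conventional_features(_vol(data), voi)
        assert feats["SUVmax"] == 20.0
        assert feats["SUVpeak"] < 20.0

    @pytest.mark.parametrize("seed", range(4))
    def test_peak_matches_exhaustive_sphere_scan(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.random((8, 8, 7)) * 12
        mask = rng.random((8, 8, 7)) < 0.4
        mask[4, 4, 3] = True
        spacing = (4.07, 4.07, 5.0)
        vol = _vol(data, spacing)
        voi = VoiMask(mask=mask, spacing=spacing)
        fast = suv_peak(vol, voi)
        slow = brute_suv_peak(data, mask, spacing, 6.2035)
        assert fast == pytest.approx(slow, rel=1e-12)


class TestShapeHistogram:
    def test_single_cube_geometry(self):
        """One 4 mm voxel: V = 64 mm^3 (0.064 mL), A = 96 mm^2, cube sphericity."""
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        feats = shape_features(VoiMask(mask=mask, spacing=(4, 4, 4)))
        assert feats["SHAPE_VolumeML"] == pytest.approx(0.064)
        assert feats["SHAPE_SurfaceMM2"] == pytest.approx(96.0)
        assert feats["SHAPE_Sphericity"] == pytest.approx(
            (36 * np.pi * 64.0**2) ** (1 / 3) / 96.0
        )
        assert feats["SHAPE_Sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3), rel=1e-9)
        assert feats["SHAPE_Compacity"] == pytest.approx(64.0 / (np.sqrt(np.pi) * 96.0**1.5))

    def test_symmetric_histogram_zero_skew(self):
        levels = np.array([1, 1, 2, 2]).reshape(4, 1, 1)
        d = DiscretizedVOI(levels=levels, mask=levels > 0, n_levels=2,
                           spacing=(4, 4, 4), config=DiscretizationConfig())
        feats = histogram_features(d)
        assert feats["HISTO_Skewness"] == pytest.approx(0.0)
        assert feats["HISTO_Entropy_log2"] == pytest.approx(1.0)
        assert feats["HISTO_Energy"] == pytest.approx(0.5)

    def test_uniform_voi_degenerate(self):
        vol, voi = uniform_voi_volume(8.0)
        d = discretize(vol, voi)
        feats = histogram_features(d)
        assert feats["HISTO_Entropy_log2"] == 0.0
        assert feats["HISTO_Energy"] == 1.0
        assert feats["HISTO_Skewness"] == 0.0


def _matrices_from_glrlm(glrlm, n_voxels=10):
    g, r = np.asarray(glrlm, float).shape
    return TextureMatrices(
        glcm_counts=np.zeros((g, g)), glcm_p=np.zeros((g, g)),
        glrlm=np.asarray(glrlm, float), ngldm=np.zeros((g, 27)),
        ngtdm_s=np.zeros(g), ngtdm_n=np.ones(g),
        glzlm=np.zeros((g, 1)), n_voxels=n_voxels, n_levels=g,
    )


class TestTextureFormulas:
    def test_glrlm_hand_arithmetic(self):
        # runs {(level 1, length 2): 1, (level 2, length 1): 1}
        m = _matrices_from_glrlm([[0, 1], [1, 0]])
        feats = glrlm_features(m)
        assert feats["GLRLM_LRLGE"] == pytest.approx(2.125)
        assert feats["GLRLM_LGRE"] == pytest.approx(0.625)
        assert feats["GLRLM_SRE"] == pytest.approx((1 / 4 + 1) / 2)
        assert feats["GLRLM_LRE"] == pytest.approx((4 + 1) / 2)

    def test_uniform_single_run_closed_form(self):
        # one grey level g=3, single runs of length L=5 in each of 13 directions
        g, L = 3, 5
        glrlm = np.zeros((g, L))
        glrlm[g - 1, L - 1] = 13
        feats = glrlm_features(_matrices_from_glrlm(glrlm, n_voxels=13 * 5 // 13))
        assert feats["GLRLM_LRLGE"] == pytest.approx(L**2 / g**2)

    def test_doubling_levels_quarters_low_level_emphases(self):
        rng = np.random.default_rng(7)
        base = rng.integers(0, 5, size=(3, 4)).astype(float)
        doubled = np.zeros((6, 4))
        doubled[1::2, :] = base  # relabel level i -> 2i
        f1 = glrlm_features(_matrices_from_glrlm(base))
        f2 = glrlm_features(_matrices_from_glrlm(doubled))
        for name in ("GLRLM_LGRE", "GLRLM_SRLGE", "GLRLM_LRLGE"):
            assert f2[name] == pytest.approx(f1[name] / 4)

    def test_uniform_voi_glcm_degenerate(self):
        vol, voi = uniform_voi_volume(8.0)
        d = discretize(vol, voi)
        feats = glcm_features(build_texture_matrices(d))
        assert feats["GLCM_ContrastVariance"] == 0.0
        assert feats["GLCM_Dissimilarity"] == 0.0
        assert feats["GLCM_Homogeneity"] == pytest.approx(1.0)
        assert feats["GLCM_Correlation"] == 0.0  # degenerate convention

    def test_checkerboard_dissimilarity_hand_computed(self):
        """2x2x2 checkerboard of levels {1,2}: the 12 edge pairs and 4 main
        diagonals connect differing levels, the 12 face diagonals equal ones."""
        idx = np.indices((2, 2, 2)).sum(axis=0)
        levels = 1 + (idx % 2)
        d = DiscretizedVOI(levels=levels, mask=np.ones((2, 2, 2), bool), n_levels=2,
                           spacing=(4, 4, 4), config=DiscretizationConfig())
        m = build_texture_matrices(d)
        feats = glcm_features(m)
        assert feats["GLCM_Dissimilarity"] == pytest.approx(16 / 28)

    def test_single_zone_sze_closed_form(self):
        vol, voi = uniform_voi_volume(8.0, n=(3, 3, 3))
        d = discretize(vol, voi)
        feats = glzlm_features(build_texture_matrices(d))
        assert feats["GLZLM_SZE"] == pytest.approx(1 / 27**2)
        assert feats["GLZLM_ZP"] == pytest.approx(1 / 27)


class TestRotationInvariance:
    @pytest.mark.parametrize("axes", [(0, 1), (0, 2), (1, 2)])
    def test_texture_features_invariant_to_90_degree_rotation(self, rng, axes):
        from conftest import random_discretized_voi

        d = random_discretized_voi(rng, shape=(5, 5, 5), n_levels=4)
        rot = DiscretizedVOI(
            levels=np.rot90(d.levels, k=1, axes=axes).copy(),
            mask=np.rot90(d.mask, k=1, axes=axes).copy(),
            n_levels=d.n_levels, spacing=d.spacing, config=d.config,
        )
        m1, m2 = build_texture_matrices(d), build_texture_matrices(rot)
        for fn in (glcm_features, glrlm_features, glzlm_features):
            f1, f2 = fn(m1), fn(m2)
            for k in f1:
                assert f1[k] == pytest.approx(f2[k], rel=1e-12), k


class TestExtractAll:
    def test_schema_and_determinism(self):
        vol, voi, _ = make_phantom(PhantomSpec(seed=3))
        r1 = extract_all(vol, voi)
        r2 = extract_all(vol, voi)
        assert tuple(r1.features) == FEATURE_NAMES
        assert len(r1.features) >= 50
        assert all(np.isfinite(v) for v in r1.features.values())
        assert r1.features == r2.features

    def test_uniform_phantom_suv_identities(self):
        spec = PhantomSpec(seed=0, falloff="uniform", heterogeneity="none",
                           noise_sd=0.0, peak_suv=9.0)
        vol, voi, _ = make_phantom(spec)
        r = extract_all(vol, voi)
        assert r.features["SUVmax"] == pytest.approx(9.0)
        assert r.features["SUVmean"] == pytest.approx(9.0)
        assert r.features["TLG"] == pytest.approx(r.features["SUVmean"] * r.features["MTV"])
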