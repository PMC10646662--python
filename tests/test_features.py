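"""Feature catalogue: conventional metrics, discretisation, texture
matrices vs brute force, filters, and structural counts."""

import numpy as np
import pytest

from petrep import (DiscretisationSpec, FilterSpec, ImageVolume, LesionMask,
                    ValidationError, apply_filter, compute_features,
                    conventional_metrics, discretise, filter_bank,
                    firstorder_features, shape_features, texture_features)
from petrep import features as ft

import oracles
from conftest import random_level_volume


class TestConventionalMetrics:
    def test_uniform_lesion(self):
        vals = np.full((5, 5, 5), 2.0)
        sup = np.zeros((5, 5, 5), bool)
        sup.ravel()[:10] = True
        img = ImageVolume(vals, (10.0, 10.0, 10.0))  # 1 mL voxels
        m = conventional_metrics(img, LesionMask(sup, "u", (10.0, 10.0, 10.0)))
        assert (m.suv_max, m.suv_mean, m.suv_total, m.volume_ml) == (2, 2, 20, 10)

    def test_single_voxel_arithmetic(self):
        vals = np.zeros((3, 3, 3))
        vals[1, 1, 1] = 7.3
        sup = vals > 0
        img = ImageVolume(vals, (4.07, 4.07, 2.0))
        m = conventional_metrics(img, LesionMask(sup, "s", (4.07, 4.07, 2.0)))
        assert m.volume_ml == pytest.approx(0.0331298, abs=1e-7)
        assert m.suv_total == pytest.approx(7.3 * 0.0331298, abs=1e-6)

    def test_equals_bruteforce_loop_and_total_identity(self, rng):
        vals = rng.random((8, 8, 8)) * 10
        sup = rng.random((8, 8, 8)) < 0.3
        sup[0, 0, 0] = True
        img = ImageVolume(vals, (2.0, 2.0, 2.0))
        m = conventional_metrics(img, LesionMask(sup, "r", (2.0, 2.0, 2.0)))
        picked = [vals[i, j, k] for i, j, k in np.argwhere(sup)]
        assert m.suv_max == max(picked)
        assert m.suv_mean == pytest.approx(sum(picked) / len(picked), rel=1e-12)
        assert m.suv_total == pytest.approx(m.suv_mean * m.volume_ml, rel=1e-15)

    def test_empty_mask_errors(self):
        img = ImageVolume(np.ones((3, 3, 3)), (1, 1, 1))
        with pytest.raises(ValidationError):
            conventional_metrics(img, LesionMask(np.zeros((3, 3, 3), bool), "e"))


class TestDiscretise:
    def test_constant_region_single_level(self):
        vals = np.full((4, 4, 4), 3.14)
        levels, n = discretise(vals, np.ones((4, 4, 4), bool))
        assert n == 1 and set(np.unique(levels)) == {1}

    def test_bin_edge_arithmetic(self):
        vals = np.array([3.0, 3.19, 3.2]).reshape(3, 1, 1)
        levels, n = discretise(vals, np.ones((3, 1, 1), bool),
                               DiscretisationSpec(bin_width=0.2))
        assert levels.ravel().tolist() == [1, 1, 2] and n == 2

    def test_translation_by_one_bin_width_is_invariant(self, rng):
        vals = rng.random((5, 5, 5)) * 4 + 1
        sup = np.ones((5, 5, 5), bool)
        a, _ = discretise(vals, sup, DiscretisationSpec(0.2))
        b, _ = discretise(vals + 0.2, sup, DiscretisationSpec(0.2))
        assert np.array_equal(a, b)


class TestTextureMatricesOracle:
    def test_two_voxel_glcm(self):
        lv = np.array([[[1]], [[2]]])
        P = ft.glcm_matrix(lv, 2)
        assert P.tolist() == [[0.0, 1.0], [1.0, 0.0]]

    def test_uniform_region_glcm_mass_on_diagonal(self):
        lv = np.ones((3, 3, 1), dtype=np.int64)
        P = ft.glcm_matrix(lv, 1)
        assert P.shape == (1, 1) and P[0, 0] > 0

    @pytest.mark.parametrize("trial", range(25))
    def test_all_families_match_bruteforce(self, trial):
        rng = np.random.default_rng(1000 + trial)
        lv, ng = random_level_volume(rng)
        assert np.allclose(ft.glcm_matrix(lv, ng), oracles.glcm_bruteforce(lv, ng), atol=1e-9)
        assert np.allclose(ft.gldm_matrix(lv, ng), oracles.gldm_bruteforce(lv, ng), atol=1e-9)
        assert np.allclose(ft.glrlm_matrix(lv, ng), oracles.glrlm_bruteforce(lv, ng), atol=1e-9)
        assert np.allclose(ft.glszm_matrix(lv, ng), oracles.glszm_bruteforce(lv, ng), atol=1e-9)
        s, n, nv = ft.ngtdm_matrix(lv, ng)
        so, no, nvo = oracles.ngtdm_bruteforce(lv, ng)
        assert np.allclose(s, so, atol=1e-9) and np.array_equal(n, no) and nv == nvo

    def test_uniform_region_degenerate_values(self, uniform_lesion):
        img, mask = uniform_lesion
        tex = texture_features(img, mask)
        # contrast-like features are 0, uniformity/correlation-like are 1
        assert tex["glcm_Contrast"] == 0.0
        assert tex["glcm_Correlation"] == 1.0
        assert tex["glcm_MCC"] == 1.0
        assert tex["glcm_JointEnergy"] == pytest.approx(1.0)
        assert tex["ngtdm_Contrast"] == 0.0
        assert tex["ngtdm_Coarseness"] == 1e6

    def test_rotational_invariance_of_merged_features(self, rng):
        lv, ng = random_level_volume(rng)
        # make the region cubic so axis rotations preserve the grid
        s = min(lv.shape)
        lv = lv[:s, :s, :s]
        if not (lv > 0).any():
            lv[0, 0, 0] = 1
        base = texture_features(lv.astype(float), lv > 0, DiscretisationSpec(1.0))
        for axes in [(0, 1), (0, 2), (1, 2)]:
            rot = np.rot90(lv, k=1, axes=axes)
            got = texture_features(rot.astype(float), rot > 0, DiscretisationSpec(1.0))
            for k in base:
                assert got[k] == pytest.approx(base[k], abs=1e-9), k


class TestFirstOrder:
    def test_uniform_mean_and_degenerates(self, uniform_lesion):
        img, mask = uniform_lesion
        fo = firstorder_features(img, mask)
        assert fo["Mean"] == 4.0
        assert fo["Variance"] == 0.0
        assert fo["Skewness"] == 0.0 and fo["Kurtosis"] == 0.0
        assert fo["Uniformity"] == 1.0 and fo["Entropy"] == pytest.approx(0.0, abs=1e-12)

    def test_moments_against_numpy(self, rng):
        vals = rng.random((6, 6, 6)) * 8 + 1
        sup = rng.random((6, 6, 6)) < 0.5
        sup[2, 2, 2] = True
        fo = firstorder_features(vals, sup, voxel_volume_mm3=8.0)
        x = vals[sup]
        assert fo["Energy"] == pytest.approx(np.sum(x**2), rel=1e-12)
        assert fo["TotalEnergy"] == pytest.approx(8.0 * np.sum(x**2), rel=1e-12)
        assert fo["RootMeanSquared"] == pytest.approx(np.sqrt(np.mean(x**2)), rel=1e-12)
        assert fo["InterquartileRange"] == pytest.approx(
            np.percentile(x, 75) - np.percentile(x, 25), rel=1e-12)


class TestShape:
    def test_sphericity_of_digital_ball_approaches_one(self):
        x, y, z = np.ogrid[:25, :25, :25]
        sup = (x - 12) ** 2 + (y - 12) ** 2 + (z - 12) ** 2 <= 100
        sh = shape_features(LesionMask(sup, "ball", (1.0, 1.0, 1.0)))
        # the marching-cubes mesh of a binary ball overestimates the surface
        # by its staircase bias, so sphericity sits below 1 but not at it
        assert 0.85 < sh["Sphericity"] < 1.0
        assert sh["MeshVolume"] == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)
        assert sh["Maximum3DDiameter"] == pytest.approx(20.0, rel=0.1)
        assert sh["Elongation"] == pytest.approx(1.0, abs=0.05)

    def test_shape_identical_across_filters(self, small_phantom):
        from petrep import resample_isotropic, resample_mask_isotropic
        _, image, masks, _ = small_phantom
        rimg = resample_isotropic(image, 2.0)
        rmask = resample_mask_isotropic(masks[0], 2.0)
        full = compute_features(rimg, rmask, filters=filter_bank())
        shape_keys = [k for k in full if "_shape_" in k]
        assert len(shape_keys) == 14
        assert all(k.startswith("original_") for k in shape_keys)


class TestFilters:
    def test_bank_enumerates_sixteen(self):
        bank = filter_bank()
        assert len(bank) == 16
        assert len({f.label for f in bank}) == 16
        kinds = [f.kind for f in bank]
        assert kinds.count("log_sigma") == 4 and kinds.count("wavelet_subband") == 8

    def test_log_of_constant_is_zero(self):
        img = ImageVolume(np.full((20, 20, 20), 5.0), (2.0, 2.0, 2.0))
        out = apply_filter(img, FilterSpec("log_sigma", sigma_mm=3.0))
        # zero up to the truncated-kernel residual of the discrete operator
        assert np.allclose(out.values, 0.0, atol=1e-3 * img.values.max())

    def test_wavelet_of_constant(self):
        img = ImageVolume(np.full((16, 16, 16), 2.0), (2.0, 2.0, 2.0))
        lll = apply_filter(img, FilterSpec("wavelet_subband", subband="LLL"))
        assert np.ptp(lll.values) == pytest.approx(0.0, abs=1e-10)
        for band in ("LLH", "HLL", "HHH"):
            det = apply_filter(img, FilterSpec("wavelet_subband", subband=band))
            assert np.allclose(det.values, 0.0, atol=1e-10)

    def test_log_response_of_gaussian_blob_matches_closed_form(self):
        # image A*exp(-r^2/(2 s^2)); LoG(sigma) at the centre is
        # -3 A s^3 / (s^2 + sigma^2)^(5/2)
        s, sigma, A = 5.0, 3.0, 10.0
        n = 61
        ax = (np.arange(n) - n // 2) * 1.0
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        img = ImageVolume(A * np.exp(-(X**2 + Y**2 + Z**2) / (2 * s**2)), (1.0, 1.0, 1.0))
        out = apply_filter(img, FilterSpec("log_sigma", sigma_mm=sigma))
        t2 = s**2 + sigma**2
        expected = -3.0 * A * s**3 / t2**2.5
        assert out.values[n // 2, n // 2, n // 2] == pytest.approx(expected, rel=0.02)

    def test_intensity_transforms_monotone_and_range_preserving(self, rng):
        v = rng.random((10, 10, 10)) * 9 + 0.5
        img = ImageVolume(v, (2.0, 2.0, 2.0))
        for kind in ("exponential", "logarithm", "square", "square_root"):
            out = apply_filter(img, FilterSpec(kind)).values
            flat_in = v.ravel()
            order = np.argsort(flat_in)
            assert np.all(np.diff(out.ravel()[order]) >= -1e-12), kind
            assert out.max() == pytest.approx(v.max(), rel=1e-9), kind

    def test_sigma_below_spacing_warns(self):
        img = ImageVolume(np.ones((8, 8, 8)), (4.0, 4.0, 4.0))
        with pytest.warns(UserWarning, match="sigma"):
            apply_filter(img, FilterSpec("log_sigma", sigma_mm=2.0))


class TestCatalogueCounts:
    def test_family_sizes_and_total(self, small_phantom):
        from petrep import resample_isotropic, resample_mask_isotropic
        _, image, masks, _ = small_phantom
        rimg = resample_isotropic(image, 2.0)
        rmask = resample_mask_isotropic(masks[0], 2.0)
        feats = compute_features(rimg, rmask)
        assert len(feats) == 107
        by_family = {}
        for k in feats:
            fam = k.split("_")[1]
            by_family[fam] = by_family.get(fam, 0) + 1
        assert by_family == {"shape": 14, "firstorder": 18, "glcm": 24,
                             "gldm": 14, "glrlm": 16, "glszm": 16, "ngtdm": 5}

    def test_full_bank_adds_1488(self, small_phantom):
        from petrep import resample_isotropic, resample_mask_isotropic
        _, image, masks, _ = small_phantom
        rimg = resample_isotropic(image, 2.0)
        rmask = resample_mask_isotropic(masks[0], 2.0)
        full = compute_features(rimg, rmask, filters=filter_bank())
        assert len(full) == 107 + 1488
        per_filter = {}
        for k in full:
            lbl = k.split("_")[0]
            per_filter[lbl] = per_filter.get(lbl, 0) + 1
        assert per_filter.pop("original") == 107
        assert set(per_filter.values()) == {93} and len(per_filter) == 16
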