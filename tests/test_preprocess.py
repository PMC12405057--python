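"""Preprocessing: denoising, CLAHE, PCA alignment, adaptive thresholding,
morphological refinement, calibration matching, and the full chain."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from skimage import transform

from beevein.preprocess import (
    CalibrationProfile,
    DESK_PROFILE,
    adaptive_threshold,
    apply_clahe,
    gaussian_blur,
    hybrid_denoise,
    match_calibration,
    otsu_threshold,
    pca_align,
    read_profiles,
    refine_mask,
    segment_image,
    write_profiles,
)
from beevein.quality import segmentation_metrics
from beevein.synthetic import STUDY_REGIMES, degrade, make_wing


class TestHybridDenoise:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 0.5)
        out = hybrid_denoise(img, DESK_PROFILE)
        assert np.allclose(out, img, atol=1e-6)

    def test_gaussian_kernel_normalized_on_impulse(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = gaussian_blur(img, CalibrationProfile())
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_even_kernel_rejected(self):
        img = np.full((32, 32), 0.5)
        bad = CalibrationProfile(gaussian_kernel=(4, 4))
        with pytest.raises(ValueError, match="odd"):
            hybrid_denoise(img, bad)

    def test_output_in_unit_range(self):
        spec = replace(STUDY_REGIMES["medium"], noise_sigma=0.1, seed=0)
        img, _ = make_wing(spec)
        out = hybrid_denoise(degrade(img, spec), DESK_PROFILE)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_unknown_order_rejected(self):
        with pytest.raises(ValueError):
            hybrid_denoise(np.full((16, 16), 0.5), DESK_PROFILE, order="both")


class TestApplyClahe:
    def test_constant_image_unchanged(self):
        img = np.full((128, 128), 0.3)
        assert np.allclose(apply_clahe(img, DESK_PROFILE), img)

    def test_low_contrast_wing_separation_increases(self):
        img, gt = make_wing(replace(STUDY_REGIMES["medium"], seed=4))
        # compress the intensity span to 0.1
        low = 0.5 + (img - img.mean()) * (0.1 / (img.max() - img.min()))
        out = apply_clahe(low, DESK_PROFILE)
        before = low[~gt.vein_mask].mean() - low[gt.vein_mask].mean()
        after = out[~gt.vein_mask].mean() - out[gt.vein_mask].mean()
        assert after > before

    def test_grid_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            apply_clahe(np.random.default_rng(0).random((10, 10)), CalibrationProfile())


class TestPcaAlign:
    @staticmethod
    def _bar_image(angle: float) -> np.ndarray:
        base = np.ones((120, 120))
        base[40:80, 57:63] = 0.0  # dark 40x6 vertical bar
        if angle:
            base = np.clip(
                transform.rotate(base, angle, cval=1.0, preserve_range=True), 0, 1
            )
        return base

    def test_vertical_bar_is_fixed_point(self):
        img = self._bar_image(0.0)
        out, angle = pca_align(img)
        assert abs(angle) <= 0.5
        assert np.abs(out - img).max() < 0.2  # unchanged up to interpolation

    def test_recovers_30_degree_rotation(self):
        out, angle = pca_align(self._bar_image(30.0))
        assert angle == pytest.approx(30.0, abs=1.0)

    def test_idempotent(self):
        out, _ = pca_align(self._bar_image(25.0))
        _, second = pca_align(out)
        assert abs(second) <= 1.0

    def test_degenerate_isotropic_foreground(self):
        img = np.ones((64, 64))
        rr, cc = np.ogrid[:64, :64]
        img[(rr - 32) ** 2 + (cc - 32) ** 2 <= 200] = 0.0  # disk: isotropic
        out, angle = pca_align(img, tol=1e-2)
        assert angle == 0.0
        assert np.array_equal(out, img)

    def test_tiny_mask_rejected(self):
        with pytest.raises(ValueError):
            pca_align(np.ones((16, 16)), mask=np.zeros((16, 16), bool))


class TestAdaptiveThreshold:
    def test_constant_image_empty_mask(self):
        assert not adaptive_threshold(np.full((64, 64), 0.5), DESK_PROFILE).any()

    def test_polarity_flag_symmetry(self):
        img, _ = make_wing(replace(STUDY_REGIMES["medium"], seed=1))
        dark = adaptive_threshold(img, DESK_PROFILE, dark_veins=True)
        light = adaptive_threshold(1.0 - img, DESK_PROFILE, dark_veins=False)
        assert np.array_equal(dark, light)

    def test_even_block_rejected(self):
        with pytest.raises(ValueError):
            adaptive_threshold(np.full((64, 64), 0.5), CalibrationProfile(thresh_block=32))

    def test_gradient_line_recovered_on_both_halves_beats_otsu(self):
        """A dark 3-px line under a strong left-right illumination ramp:
        adaptive thresholding keeps the line on both halves while the
        global Otsu threshold loses it on one side."""
        rows, cols = 96, 192
        ramp = np.tile(np.linspace(0.35, 0.95, cols), (rows, 1))
        img = ramp.copy()
        img[46:49, 8:184] -= 0.3
        img = np.clip(img, 0, 1)
        gt = np.zeros((rows, cols), bool)
        gt[46:49, 8:184] = True
        ada = adaptive_threshold(img, DESK_PROFILE)
        ots = otsu_threshold(img)
        f_ada = segmentation_metrics(ada, gt).f1
        f_ots = segmentation_metrics(ots, gt).f1
        assert ada[47, 20] and ada[47, 170]  # recovered on both halves
        assert f_ada > f_ots


class TestRefineMask:
    def test_small_blob_removed(self):
        m = np.zeros((32, 32), bool)
        m[4:7, 4:7] = True  # 9 px < 10
        assert not refine_mask(m, CalibrationProfile()).any()

    def test_one_pixel_gap_bridged(self):
        m = np.zeros((16, 64), bool)
        m[7:10, 4:30] = True
        m[7:10, 31:60] = True  # 1-px gap at col 30
        out = refine_mask(m, CalibrationProfile())
        assert out[8, 30]

    def test_large_bar_stable(self):
        m = np.zeros((24, 80), bool)
        m[10:13, 10:60] = True
        out = refine_mask(m, CalibrationProfile())
        inner = np.zeros_like(m)
        inner[11, 12:58] = True
        assert (out & inner).sum() == inner.sum()  # interior intact
        assert np.abs(out.sum() - m.sum()) <= 0.25 * m.sum()  # boundary only

    def test_no_component_below_minimum_survives(self):
        rng = np.random.default_rng(0)
        from scipy import ndimage

        m = ndimage.gaussian_filter(rng.random((96, 96)), 2) > 0.55
        out = refine_mask(m, DESK_PROFILE)
        labels, n = ndimage.label(out, structure=np.ones((3, 3)))
        sizes = np.bincount(labels.ravel())[1:]
        assert (sizes >= DESK_PROFILE.min_component_px).all()

    def test_empty_mask_passes_through(self):
        assert not refine_mask(np.zeros((16, 16), bool), CalibrationProfile()).any()


class TestMatchCalibration:
    @staticmethod
    def _profile_for(img, pid):
        h, _ = np.histogram(img, bins=256, range=(0, 1))
        return CalibrationProfile(
            profile_id=pid, reference_histogram=tuple(h / h.sum())
        )

    def test_self_match_wins(self):
        img_a, _ = make_wing(replace(STUDY_REGIMES["sparse"], seed=1))
        img_b = np.clip(img_a * 0.3 + 0.6, 0, 1)
        a = self._profile_for(img_a, "a")
        b = self._profile_for(img_b, "b")
        assert match_calibration(img_a, [b, a]).profile_id == "a"

    def test_single_profile_returned(self):
        img, _ = make_wing(STUDY_REGIMES["sparse"])
        p = self._profile_for(img, "only")
        assert match_calibration(img, [p]).profile_id == "only"

    def test_mixture_follows_dominant_component(self):
        rng = np.random.default_rng(3)
        # orthogonal histograms: low-intensity vs high-intensity populations
        img_a = rng.uniform(0.0, 0.4, (64, 64))
        img_b = rng.uniform(0.6, 1.0, (64, 64))
        a, b = self._profile_for(img_a, "a"), self._profile_for(img_b, "b")
        mix = np.where(rng.random((64, 64)) < 0.6, img_a, img_b)
        assert match_calibration(mix, [a, b]).profile_id == "a"

    def test_no_histograms_falls_back_to_first(self):
        img, _ = make_wing(STUDY_REGIMES["sparse"])
        p1, p2 = CalibrationProfile(profile_id="p1"), CalibrationProfile(profile_id="p2")
        assert match_calibration(img, [p1, p2]).profile_id == "p1"

    def test_empty_profile_list_rejected(self):
        with pytest.raises(ValueError):
            match_calibration(np.full((8, 8), 0.5), [])


class TestProfilesCsv:
    def test_round_trip(self, tmp_path):
        img, _ = make_wing(STUDY_REGIMES["sparse"])
        h, _ = np.histogram(img, bins=256, range=(0, 1))
        profiles = [
            CalibrationProfile(),
            replace(DESK_PROFILE, reference_histogram=tuple(h / h.sum())),
        ]
        path = tmp_path / "filter_params.csv"
        write_profiles(profiles, path)
        back = read_profiles(path)
        assert [p.profile_id for p in back] == ["default", "synthetic_desk"]
        assert back[1].nlm_search_window == DESK_PROFILE.nlm_search_window
        assert back[1].thresh_c == DESK_PROFILE.thresh_c
        np.testing.assert_allclose(back[1].reference_histogram, profiles[1].reference_histogram)

    def test_shipped_profiles_parse(self):
        from pathlib import Path

        cfg = Path(__file__).resolve().parents[1] / "configs" / "filter_params.csv"
        profiles = read_profiles(cfg)
        ids = {p.profile_id for p in profiles}
        assert {"default", "synthetic_desk"} <= ids


class TestFullChain:
    def test_clean_wing_f1(self):
        """Full preprocessing chain on clean synthetic wings reaches
        pixelwise F1 >= 0.85 against the generator's ground truth."""
        scores = []
        for name in ("sparse", "medium", "dense"):
            img, gt = make_wing(replace(STUDY_REGIMES[name], seed=2))
            mask = segment_image(img, DESK_PROFILE)
            scores.append(segmentation_metrics(mask, gt.vein_mask).f1)
        assert min(scores) >= 0.85

    def test_shape_and_range_preserved(self):
        spec = replace(STUDY_REGIMES["medium"], seed=3)
        img, _ = make_wing(spec)
        deg = degrade(img, spec)
        for op in (
            lambda x: hybrid_denoise(x, DESK_PROFILE),
            lambda x: apply_clahe(x, DESK_PROFILE),
            lambda x: pca_align(x)[0],
        ):
            out = op(deg)
            assert out.shape == deg.shape
            assert out.min() >= 0.0 and out.max() <= 1.0
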