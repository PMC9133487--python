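"""Surface segmentation, outlier rejection, flattening, en-face, masks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from visoct.layers import (
    LayerSurfaces,
    SegmentationConfig,
    detect_rpe_raw,
    flatten,
    make_enface,
    refine_curve,
    reject_bscan_outliers,
    repair_enface_rows,
    segment_rpe,
    unflatten,
    vessel_mask,
)


def cubic(n=128, coeffs=(60.0, 8.0, -4.0, 2.0)):
    x = np.linspace(-1, 1, n)
    c0, c1, c2, c3 = coeffs
    return c0 + c1 * x + c2 * x**2 + c3 * x**3


class TestDetectRpeRaw:
    def test_bright_rpe_detected_on_clean_phantom(self, clean_artery):
        """Away from degradations the blurred argmax lands on the RPE
        (surface curvature under the sigma-7 blur costs < 2 px)."""
        truth = clean_artery["truth"]
        raw = clean_artery["surfaces"].rpe_raw
        err = np.abs(raw - truth.rpe_depth)
        assert np.nanmax(err) <= 2.0
        assert np.nanmedian(err) <= 1.0

    def test_bright_superficial_reflector_hijacks_argmax(self):
        """An A-line whose inner retina outshines the RPE yields a raw
        detection on the superficial layer — the outlier the refinement
        stage exists to repair."""
        B, A, D = 1, 64, 128
        vol = np.zeros((B, A, D))
        vol[0, :, 90] = 1.0  # RPE plane
        vol[0, 30, 25] = 60.0  # saturated superficial glint
        raw = detect_rpe_raw(vol, SegmentationConfig())
        assert abs(raw[0, 30] - 25) < 8
        far = np.abs(raw[0, :15] - 90)
        assert far.max() <= 1

    def test_spike_glints_corrupt_a_fraction_of_alines(self, degraded):
        """Saturated glints corrupt a few percent of raw detections on
        the valid B-scans of the degraded phantom."""
        truth = degraded["truth"]
        raw = degraded["surfaces"].rpe_raw
        ok = ~np.isin(np.arange(truth.rpe_depth.shape[0]), truth.corrupt_bscans)
        frac = (np.abs(raw - truth.rpe_depth)[ok] > 5).mean()
        assert 0.01 < frac < 0.15

    def test_all_zero_aline_flagged_missing(self):
        vol = np.ones((1, 4, 64))
        vol[0, 2] = 0.0
        raw = detect_rpe_raw(vol, SegmentationConfig(blur_sigma=1))
        assert np.isnan(raw[0, 2])
        assert np.isfinite(raw[0, [0, 1, 3]]).all()


class TestRefineCurve:
    def test_perfect_cubic_untouched(self):
        y = cubic()
        fitted, flags = refine_curve(y)
        assert not flags.any()
        assert np.allclose(fitted, y, atol=1e-8)

    def test_injected_spikes_flagged_and_repaired(self):
        y = cubic()
        spikes = [10, 30, 55, 80, 120]
        y2 = y.copy()
        y2[spikes] += 40.0
        fitted, flags = refine_curve(y2)
        assert set(np.nonzero(flags)[0]) == set(spikes)
        assert np.abs(fitted - y).max() < 1.0

    def test_termination_and_monotone_inliers(self):
        rng = np.random.default_rng(0)
        y = cubic() + rng.normal(0, 3, 128)
        cfg = SegmentationConfig(max_iter=50)
        fitted, flags = refine_curve(y, cfg)
        assert fitted.shape == y.shape
        # flags only ever removes points; on its own output it is a no-op
        y_clean = fitted.copy()
        fitted2, flags2 = refine_curve(y_clean, cfg)
        assert not flags2.any()
        assert np.allclose(fitted2, fitted, atol=1e-6)

    def test_too_few_points_errors_with_bscan_name(self):
        with pytest.raises(ValueError, match="B-scan 17"):
            refine_curve(np.array([1.0, 2.0, np.nan, np.nan]), bscan_index=17)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=127), min_size=1, max_size=6, unique=True))
    def test_spike_positions_never_break_termination(self, spikes):
        """The delete-and-refit loop terminates and flags only spikes,
        wherever they are placed along the curve."""
        y = cubic()
        y[spikes] += 35.0
        fitted, flags = refine_curve(y)
        assert flags.sum() <= len(spikes) + 2
        assert np.abs(fitted - cubic()).max() < 3.0


class TestCovRejection:
    def test_identical_covs_keep_everything(self):
        fit = np.tile(cubic(32), (10, 1))
        surfaces = LayerSurfaces(
            rpe_raw=fit.copy(), rpe_fit=fit.copy(),
            outlier_mask=np.zeros((10, 32), bool),
            cov_trace=np.full(10, 0.05),
        )
        out = reject_bscan_outliers(surfaces)
        assert out.replaced_bscans == ()
        assert np.array_equal(out.rpe_fit, fit)

    def test_corrupt_bscans_flagged_exactly(self, degraded):
        """The COV rule flags precisely the two corrupted B-scans of the
        noiseless degraded phantom."""
        assert degraded["surfaces"].replaced_bscans == (20, 40)

    def test_replacement_preserves_bscan_count_and_uses_neighbor(self):
        fit = np.tile(cubic(32), (10, 1))
        fit[4] = fit[4] + np.linspace(-30, 30, 32)  # wildly tilted curve
        cov = fit.std(axis=1) / fit.mean(axis=1)
        surfaces = LayerSurfaces(
            rpe_raw=fit.copy(), rpe_fit=fit.copy(),
            outlier_mask=np.zeros((10, 32), bool), cov_trace=cov,
        )
        out = reject_bscan_outliers(surfaces)
        assert out.rpe_fit.shape == fit.shape
        assert out.replaced_bscans == (4,)
        assert np.array_equal(out.rpe_fit[4], fit[3])

    def test_first_bscan_uses_next_valid_curve(self):
        fit = np.tile(cubic(32), (6, 1))
        fit[0] = fit[0] + np.linspace(-40, 40, 32)
        cov = fit.std(axis=1) / fit.mean(axis=1)
        surfaces = LayerSurfaces(
            rpe_raw=fit.copy(), rpe_fit=fit.copy(),
            outlier_mask=np.zeros((6, 32), bool), cov_trace=cov,
        )
        out = reject_bscan_outliers(surfaces)
        assert 0 in out.replaced_bscans
        assert np.array_equal(out.rpe_fit[0], fit[1])


class TestFlatten:
    def test_constant_rpe_is_identity(self):
        vol = np.random.default_rng(0).random((3, 5, 32))
        flat, shifts = flatten(vol, np.full((3, 5), 20.0), target_row=20)
        assert np.array_equal(flat, vol)
        assert np.all(shifts == 0)

    def test_tilted_plane_flattens_to_zero_variance(self):
        B, A, D = 4, 16, 64
        vol = np.zeros((B, A, D))
        rpe = 30.0 + np.tile(np.arange(A) * 0.5, (B, 1))
        for x in range(B):
            for y in range(A):
                vol[x, y, int(round(rpe[x, y]))] = 1.0
        flat, shifts = flatten(vol, rpe)
        rows = flat.argmax(axis=-1)
        assert rows.std() == 0

    def test_unflatten_inverts_exactly(self):
        vol = np.random.default_rng(1).random((3, 5, 32))
        rpe = np.random.default_rng(2).integers(5, 25, (3, 5)).astype(float)
        flat, shifts = flatten(vol, rpe)
        assert np.array_equal(unflatten(flat, shifts), vol)


class TestIlm:
    def test_ilm_above_rpe_everywhere(self, clean_artery):
        assert np.all(clean_artery["ilm"] < clean_artery["surfaces"].rpe_fit)

    def test_ilm_matches_truth(self, clean_artery):
        err = np.abs(clean_artery["ilm"] - clean_artery["truth"].ilm_depth)
        assert np.percentile(err, 99) <= 2.0


class TestEnface:
    def test_constant_volume_gives_constant_image(self):
        vol = np.full((3, 4, 64), 2.5)
        rpe = np.full((3, 4), 40.0)
        img = make_enface(vol, rpe)
        assert np.allclose(img, 2.5)

    def test_band_clipped_at_top_without_error(self):
        vol = np.ones((2, 3, 32))
        rpe = np.full((2, 3), 5.0)  # band would start above the volume
        img = make_enface(vol, rpe, SegmentationConfig(enface_band_px=20, enface_guard_px=0))
        assert np.isfinite(img).all()

    def test_vessel_shadow_is_local_minimum(self, clean_artery):
        truth = clean_artery["truth"]
        enface = clean_artery["enface"]
        inside = enface[truth.vessel_masks[0]].mean()
        outside = enface[~truth.vessel_masks[0]].mean()
        assert inside < 0.5 * outside

    def test_repair_replaces_flagged_rows(self):
        img = np.ones((5, 4))
        img[2] = 99.0
        out = repair_enface_rows(img, (2,))
        assert np.allclose(out[2], 1.0)
        assert np.allclose(out[[0, 1, 3, 4]], 1.0)


class TestVesselMask:
    def test_blank_image_gives_empty_mask(self):
        assert not vessel_mask(np.zeros((32, 32))).any()
        assert not vessel_mask(np.full((32, 32), 3.0)).any()

    def test_phantom_vessels_recovered(self, two_vessel):
        """Adaptive threshold recovers the vessel shadows (Dice >= 0.7)."""
        truth = two_vessel["truth"]
        detected = two_vessel["detected_mask"]
        tm = np.zeros_like(detected)
        for m in truth.vessel_masks:
            tm |= m
        dice = 2 * np.sum(detected & tm) / (detected.sum() + tm.sum())
        assert dice >= 0.7

    def test_tiny_objects_removed(self):
        rng = np.random.default_rng(5)
        img = 10.0 + 0.01 * rng.standard_normal((64, 64))
        img[10, 10] = 0.1  # single dark pixel: a child vessel too small to keep
        mask = vessel_mask(img)
        assert not mask.any()


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [dict(outlier_k=0.0), dict(poly_order=0)])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SegmentationConfig(**kw)

    def test_degraded_surface_rms(self, degraded):
        """With spikes and corrupt B-scans the refined surfaces stay
        within 2 px RMS of truth on the valid B-scans."""
        truth = degraded["truth"]
        surfaces = degraded["surfaces"]
        ok = ~np.isin(np.arange(truth.rpe_depth.shape[0]), truth.corrupt_bscans)
        rpe_rms = np.sqrt(np.mean((surfaces.rpe_fit[ok] - truth.rpe_depth[ok]) ** 2))
        ilm_rms = np.sqrt(np.mean((degraded["ilm"][ok] - truth.ilm_depth[ok]) ** 2))
        assert rpe_rms <= 2.0
        assert ilm_rms <= 2.0
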