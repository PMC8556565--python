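"""Layer segmentation: operators, detectors, artifact correction, pipeline."""

import numpy as np
import pytest

import octretina as ot
from octretina.phantom import PhantomConfig, make_phantom
from octretina.segmentation import (
    BOUNDARY_NAMES,
    BoundarySurface,
    SegmentationError,
    SegmentationParams,
    axial_derivative,
    correct_boundary,
    denoise,
    detect_ipl_inl,
    detect_nfl_ipl,
    detect_onh,
    detect_opl,
    detect_os,
    detect_rpe,
    detect_vitreous_nfl,
    segment_retina,
)


class TestDenoise:
    def test_unit_kernel_is_identity(self):
        v = np.random.default_rng(0).random((2, 10, 6))
        assert np.array_equal(denoise(v, (1, 1)), v)

    def test_constant_image_unchanged(self):
        assert np.allclose(denoise(np.full((1, 8, 8), 3.0), (3, 3)), 3.0)

    def test_impulse_spreads_to_uniform_patch(self):
        v = np.zeros((1, 9, 9))
        v[0, 4, 4] = 1.0
        out = denoise(v, (3, 3))
        assert np.allclose(out[0, 3:6, 3:6], 1 / 9)
        assert np.isclose(out.sum(), 1.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            denoise(np.zeros((1, 4, 4)), (2, 3))


class TestAxialDerivative:
    def test_linear_ramp_gives_constant_slope(self):
        z = np.arange(20.0)
        v = np.broadcast_to((2.5 * z)[None, :, None], (1, 20, 3)).copy()
        assert np.allclose(axial_derivative(v), 2.5)

    def test_constant_gives_zero(self):
        assert not axial_derivative(np.full((1, 10, 2), 4.0)).any()

    def test_step_peak_at_transition(self):
        v = np.zeros((1, 30, 1))
        v[0, 15:] = 10.0
        D = axial_derivative(v)
        assert int(np.argmax(D[0, :, 0])) in (14, 15)


class TestDetectors:
    def test_rpe_exact_on_noise_free(self, noise_free):
        vol, truth = noise_free
        sm = denoise(vol.data.mean(axis=1), (3, 11))
        rpe = detect_rpe(sm)
        centre = truth.boundaries["RPE_posterior"] - 3.0
        assert np.nanmax(np.abs(rpe.depth - centre)) <= 1.0

    def test_rpe_tie_resolves_anterior(self):
        v = np.zeros((1, 20, 1))
        v[0, 5] = v[0, 12] = 1.0
        assert detect_rpe(v).depth[0, 0] == 5.0

    def test_rpe_nan_without_signal(self):
        v = np.zeros((1, 20, 2))
        v[0, :, 1] = np.nan
        d = detect_rpe(v).depth
        assert np.isnan(d).all()

    def test_onh_absent_gives_empty_mask(self, noise_free):
        vol, _ = noise_free
        sm = denoise(vol.data.mean(axis=1), (3, 3))
        onh = detect_onh(sm, detect_rpe(sm), SegmentationParams())
        assert onh.width_px == 0.0
        assert not onh.mask.any()

    def test_onh_width_and_centre_recovered(self, study_seg):
        seg, truth = study_seg
        cfg = ot.study_config(seed=1)
        assert abs(seg.onh.width_px - truth.onh_width_px) <= 2.0
        assert np.hypot(seg.onh.center[0] - cfg.onh_center_xy[0],
                        seg.onh.center[1] - cfg.onh_center_xy[1]) <= 2.0

    def test_vitreous_nfl_noise_free(self, noise_free):
        vol, truth = noise_free
        sm = denoise(vol.data.mean(axis=1), (3, 11))
        D = axial_derivative(sm)
        rpe = detect_rpe(sm)
        surf = detect_vitreous_nfl(sm, D, rpe, SegmentationParams())
        assert np.nanmax(np.abs(surf.depth - truth.boundaries["vitreous_NFL"])) <= 1.0

    def test_pure_vitreous_aline_is_nan(self):
        # flat zero volume with a bright band: A-lines beyond the band edge
        v = np.full((1, 200, 4), 0.01)
        v[0, 150:156, :2] = 1.0  # retina only on first two A-lines
        D = axial_derivative(v)
        params = SegmentationParams(retina_margin_um=25.0)
        rpe = BoundarySurface("RPE_center", np.full((1, 4), 152.0))
        surf = detect_vitreous_nfl(v, D, rpe, params)
        assert np.isnan(surf.depth[0, 2:]).all()

    def test_opl_all_ones_weight_equals_plain_argmax(self, noise_free):
        """With the Hann weighting disabled the detector is a windowed argmax."""
        vol, _ = noise_free
        sm = denoise(vol.data.mean(axis=1), (3, 11))
        D = axial_derivative(sm)
        params = SegmentationParams(hann_length_px=10**6)  # forces fallback
        rpe = detect_rpe(sm)
        vnfl = detect_vitreous_nfl(sm, D, rpe, params)
        got = detect_opl(sm, vnfl, rpe, params)
        lo = vnfl.depth + params.opl_search_fraction * (rpe.depth - vnfl.depth)
        hi = rpe.depth - params.rpe_band_halfwidth_px
        z = np.arange(sm.shape[1])
        for a in (0, 31, 63):
            win = (z > lo[0, a]) & (z < hi[0, a])
            expected = z[win][np.argmax(sm[0, win, a])]
            assert abs(got.depth[0, a] - expected) <= 0.5

    def test_opl_flat_profile_flagged_low_confidence(self):
        v = np.full((1, 300, 3), 1.0)
        v[0, 250:256] = 5.0  # RPE band only
        params = SegmentationParams()
        rpe = BoundarySurface("RPE_center", np.full((1, 3), 252.0))
        vnfl = BoundarySurface("vitreous_NFL", np.full((1, 3), 100.0))
        got = detect_opl(v, vnfl, rpe, params)
        assert got.low_confidence.all()

    def test_ipl_inl_window_width_one(self):
        D = np.zeros((1, 50, 1))
        D[0, 20] = -5.0
        vnfl = BoundarySurface("vitreous_NFL", np.full((1, 1), 19.0))
        opl = BoundarySurface("OPL", np.full((1, 1), 21.0))
        got = detect_ipl_inl(None, D, vnfl, opl)
        assert got.depth[0, 0] == 20.0

    def test_nfl_ipl_robust_to_doubled_prior(self, noise_free):
        """A 2x-wrong NFL thickness prior still lands within 2 px."""
        vol, truth = noise_free
        sm = denoise(vol.data.mean(axis=1), (3, 11))
        D = axial_derivative(sm)
        params = SegmentationParams(nfl_prior_um=36.0)
        rpe = detect_rpe(sm)
        vnfl = detect_vitreous_nfl(sm, D, rpe, params)
        opl = detect_opl(sm, vnfl, rpe, params)
        ipl_inl = detect_ipl_inl(sm, D, vnfl, opl, params)
        got = detect_nfl_ipl(sm, D, vnfl, ipl_inl, params)
        assert np.nanmean(np.abs(got.depth - truth.boundaries["NFL_IPL"])) <= 2.0

    def test_zero_thickness_nfl_collapses_to_surface(self):
        D = np.zeros((1, 60, 1))
        vnfl = BoundarySurface("vitreous_NFL", np.full((1, 1), 10.0))
        ipl_inl = BoundarySurface("IPL_INL", np.full((1, 1), 40.0))
        got = detect_nfl_ipl(None, D, vnfl, ipl_inl, SegmentationParams())
        assert got.depth[0, 0] == 10.0
        assert got.low_confidence[0, 0]

    def test_os_window_width_one(self):
        D = np.zeros((1, 50, 1))
        opl = BoundarySurface("OPL", np.full((1, 1), 29.0))
        rpe = BoundarySurface("RPE_center", np.full((1, 1), 34.0))
        got = detect_os(None, D, opl, rpe, SegmentationParams())
        assert got.depth[0, 0] == 30.0

    def test_os_noise_free(self, noise_free):
        vol, truth = noise_free
        sm = denoise(vol.data.mean(axis=1), (3, 11))
        D = axial_derivative(sm)
        rpe = detect_rpe(sm)
        params = SegmentationParams()
        vnfl = detect_vitreous_nfl(sm, D, rpe, params)
        opl = detect_opl(sm, vnfl, rpe, params)
        got = detect_os(sm, D, opl, rpe, params)
        assert np.nanmax(np.abs(got.depth - truth.boundaries["OS_anterior"])) <= 1.0


class TestCorrectBoundary:
    params = SegmentationParams(poly_order=4, sd_threshold=2.0)

    def test_polynomial_surface_is_fixed_point(self):
        x = np.arange(64.0)
        depth = np.broadcast_to(100 + 0.01 * (x - 32) ** 2, (3, 64)).copy()
        out = correct_boundary(BoundarySurface("OPL", depth), self.params)
        assert np.allclose(out.depth, depth, atol=1e-6)

    def test_spike_replaced_by_fit(self):
        """Flat surface + one 20-px spike: only the spike is corrected."""
        depth = np.full((1, 64), 120.0)
        depth[0, 30] = 140.0
        out = correct_boundary(BoundarySurface("OPL", depth.copy()), self.params)
        # oracle: direct polynomial fit + residual rule
        fit = np.polynomial.Polynomial.fit(np.arange(64.0), depth[0], 4)(np.arange(64.0))
        res = depth[0] - fit
        sd = res.std()
        expected = np.where(np.abs(res) <= 2 * sd, depth[0], fit)
        assert np.allclose(out.depth[0], expected)
        assert abs(out.depth[0, 30] - 120.0) < 3.0
        untouched = np.delete(np.arange(64), 30)
        assert np.allclose(out.depth[0, untouched], 120.0, atol=1.0)

    def test_uniform_offset_absorbed_by_fit(self):
        x = np.arange(64.0)
        depth = (100 + 0.2 * x)[None, :]
        out1 = correct_boundary(BoundarySurface("OPL", depth.copy()), self.params)
        out2 = correct_boundary(BoundarySurface("OPL", depth + 5.0), self.params)
        assert np.allclose(out2.depth, out1.depth + 5.0, atol=1e-6)

    def test_nans_filled_from_fit(self):
        x = np.arange(64.0)
        depth = (100 + 0.5 * x)[None, :].copy()
        depth[0, 10:15] = np.nan
        out = correct_boundary(BoundarySurface("OPL", depth), self.params)
        assert np.allclose(out.depth[0, 10:15], 100 + 0.5 * x[10:15], atol=1e-6)

    def test_deficient_bscan_takes_nearest_fit_and_flags(self):
        depth = np.broadcast_to(np.full(64, 80.0), (3, 64)).copy()
        depth[1] = np.nan
        out = correct_boundary(BoundarySurface("OPL", depth), self.params)
        assert np.allclose(out.depth[1], 80.0, atol=1e-6)
        assert out.low_confidence[1].all()

    def test_all_bscans_deficient_raises(self):
        depth = np.full((2, 10), np.nan)
        with pytest.raises(SegmentationError):
            correct_boundary(BoundarySurface("OPL", depth), self.params)


class TestSegmentRetina:
    def test_noise_free_recovers_all_boundaries(self, noise_free_seg):
        """Every boundary within 1 px of truth at every A-line."""
        seg, truth = noise_free_seg
        for name in BOUNDARY_NAMES:
            err = np.abs(seg.boundaries[name].depth - truth.boundaries[name])
            assert np.nanmax(err) <= 1.0, name
            assert np.isfinite(seg.boundaries[name].depth).all()

    def test_speckled_mae_within_one_pixel(self, study_seg):
        seg, truth = study_seg
        outside = ~(truth.onh_mask | truth.vessel_mask)
        for name in BOUNDARY_NAMES:
            err = np.abs(seg.boundaries[name].depth - truth.boundaries[name])
            assert np.nanmean(err[outside]) <= 1.0, name

    def test_no_boundaries_inside_onh(self, study_seg):
        seg, _ = study_seg
        for name in BOUNDARY_NAMES:
            assert np.isnan(seg.boundaries[name].depth[seg.onh.mask]).all()
        assert not seg.valid_mask[seg.onh.mask].any()

    def test_boundary_ordering_invariant(self, study_seg):
        seg, _ = study_seg
        stack = np.stack([seg.boundaries[n].depth for n in BOUNDARY_NAMES])
        diffs = np.diff(stack, axis=0)
        assert np.nanmin(diffs) >= 0.0

    def test_deterministic(self, study):
        vol, _ = study
        s1 = segment_retina(vol)
        s2 = segment_retina(vol)
        for name in BOUNDARY_NAMES:
            assert np.array_equal(s1.boundaries[name].depth,
                                  s2.boundaries[name].depth, equal_nan=True)

    def test_axial_shift_equivariance(self, noise_free):
        """Shifting the volume down k pixels shifts every boundary by k."""
        vol, _ = noise_free
        k = 7
        seg0 = segment_retina(vol)
        shifted = vol.with_data(np.roll(vol.data, k, axis=2))
        seg1 = segment_retina(shifted)
        for name in BOUNDARY_NAMES:
            delta = seg1.boundaries[name].depth - seg0.boundaries[name].depth
            assert np.nanmax(np.abs(delta - k)) < 0.01, name

    def test_no_signal_raises(self):
        vol = ot.OCTVolume(np.zeros((4, 2, 100, 16)), 2.53, 6.25)
        with pytest.raises(SegmentationError, match="RPE"):
            segment_retina(vol)

    def test_randomized_phantoms_keep_ordering(self):
        rng = np.random.default_rng(12)
        for _ in range(3):
            t = {"NFL": rng.uniform(10, 25), "IPL": rng.uniform(35, 60),
                 "INL": rng.uniform(20, 40), "ORL": rng.uniform(60, 95),
                 "RPE_Bruch": 15.2}
            cfg = PhantomConfig(
                n_alines=48, n_bscans=16, n_depth=320,
                layer_thicknesses_um={k: float(v) for k, v in t.items()},
                seed=int(rng.integers(1 << 16)),
            )
            vol, _ = make_phantom(cfg)
            seg = segment_retina(vol)
            stack = np.stack([seg.boundaries[n].depth for n in BOUNDARY_NAMES])
            assert np.nanmin(np.diff(stack, axis=0)) >= 0.0
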