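"""Thickness maps, ROI selection and ONH band morphometry."""

import numpy as np
import pytest

import octretina as ot
from octretina.morphometry import (
    LAYER_DEFINITIONS,
    RoiSpec,
    axial_scale,
    band_difference,
    band_rois,
    roi_thickness,
    select_roi,
    thickness_map,
    thickness_table,
)


class TestAxialScale:
    def test_study_values(self):
        """3.42 um/px in air at n = 1.35 gives 2.53 um/px in tissue."""
        assert round(axial_scale(3.42, 1.35), 2) == 2.53

    def test_unit_index_identity(self):
        assert axial_scale(7.7, 1.0) == 7.7

    def test_hand_division(self):
        assert round(axial_scale(3.42, 1.38), 3) == 2.478

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            axial_scale(0.0, 1.35)
        with pytest.raises(ValueError):
            axial_scale(3.42, -1.0)


class TestThicknessMap:
    def test_identical_surfaces_zero(self, noise_free_seg):
        seg, _ = noise_free_seg
        m = thickness_map(seg, "vitreous_NFL", "NFL_IPL", 2.53)
        same = (seg.boundaries["NFL_IPL"].depth
                - seg.boundaries["vitreous_NFL"].depth) * 2.53
        assert np.allclose(m, same, equal_nan=True)

    def test_reversed_pair_rejected(self, noise_free_seg):
        seg, _ = noise_free_seg
        with pytest.raises(ValueError, match="anterior"):
            thickness_map(seg, "OPL", "vitreous_NFL", 2.53)

    def test_noise_free_nfl_matches_configuration(self, noise_free_seg):
        seg, truth = noise_free_seg
        scale = 3.42 / 1.35
        m = thickness_map(seg, "vitreous_NFL", "NFL_IPL", scale)
        expected = truth.layer_thickness_um("vitreous_NFL", "NFL_IPL", scale)
        assert np.nanmax(np.abs(m - expected)) <= 1.0 * scale

    def test_layers_partition_total_exactly(self, study_seg):
        """NFL + IPL + INL + ORL = total, by construction."""
        seg, _ = study_seg
        scale = 2.53
        parts = sum(
            thickness_map(seg, *LAYER_DEFINITIONS[layer], scale)
            for layer in ("NFL", "IPL", "INL", "ORL")
        )
        total = thickness_map(seg, *LAYER_DEFINITIONS["total"], scale)
        assert np.allclose(parts, total, equal_nan=True, atol=1e-9)

    def test_scaling_linearity(self, noise_free_seg):
        seg, _ = noise_free_seg
        m1 = thickness_map(seg, "vitreous_NFL", "RPE_posterior", 2.53)
        m2 = thickness_map(seg, "vitreous_NFL", "RPE_posterior", 5.06)
        assert np.allclose(m2, 2 * m1, equal_nan=True)


class TestSelectRoi:
    def test_empty_masks_pick_field_centre(self):
        empty = np.zeros((21, 31), bool)
        roi = select_roi(empty, empty, radius_um=10.0, lateral_scale_um=5.0)
        assert roi.center == (10.0, 15.0)

    def test_single_free_disk_found(self):
        """Exhaustive-scan oracle: only one feasible disk remains."""
        excluded = np.ones((40, 40), bool)
        excluded[10:21, 24:35] = False  # free 11x11 patch around (15, 29)
        roi = select_roi(excluded, np.zeros_like(excluded),
                         radius_um=4.0, lateral_scale_um=1.0)
        assert roi.center == (15.0, 29.0)

    def test_radius_exceeding_fov_rejected(self):
        empty = np.zeros((10, 10), bool)
        with pytest.raises(ValueError, match="field of view"):
            select_roi(empty, empty, radius_um=100.0, lateral_scale_um=1.0)

    def test_fully_excluded_rejected(self):
        full = np.ones((20, 20), bool)
        with pytest.raises(ValueError, match="feasible"):
            select_roi(full, np.zeros_like(full), 2.0, 1.0)


class TestRoiThickness:
    def test_constant_map(self):
        roi = RoiSpec(center=(10.0, 10.0), radius_um=5.0, radius_px=5.0)
        mean, n = roi_thickness(np.full((21, 21), 42.0), roi)
        assert mean == 42.0
        assert n == 81  # pixels in a radius-5 disk

    def test_half_split_averages_to_midpoint(self):
        m = np.full((21, 21), 10.0)
        m[:, 11:] = 20.0  # split right of centre column
        roi = RoiSpec(center=(10.0, 10.5), radius_um=6.0, radius_px=6.0)
        mean, _ = roi_thickness(m, roi)
        assert abs(mean - 15.0) < 1.0

    def test_nan_pixels_reduce_count(self):
        m = np.full((21, 21), 5.0)
        m[10, 10] = np.nan
        roi = RoiSpec(center=(10.0, 10.0), radius_um=3.0, radius_px=3.0)
        mean, n = roi_thickness(m, roi)
        assert mean == 5.0
        full_n = roi_thickness(np.full((21, 21), 5.0), roi)[1]
        assert n == full_n - 1

    def test_all_nan_rejected(self):
        roi = RoiSpec(center=(5.0, 5.0), radius_um=2.0, radius_px=2.0)
        with pytest.raises(ValueError):
            roi_thickness(np.full((11, 11), np.nan), roi)


class TestBands:
    def test_disjoint_annuli_of_configured_width(self):
        """Geometry oracle: fov radius 250 um, ONH radius 50 um, bands 55 um."""
        scale = 5.0  # um per px
        adjacent, distal = band_rois(
            onh_center=(50.0, 50.0), onh_radius_px=10.0, lateral_scale_um=scale,
            shape=(101, 101), band_um=55.0, fov_radius_um=250.0,
        )
        assert not (adjacent & distal).any()
        ii, jj = np.meshgrid(np.arange(101.0), np.arange(101.0), indexing="ij")
        rr = np.hypot(ii - 50, jj - 50) * scale
        assert rr[adjacent].min() >= 50.0 and rr[adjacent].max() < 105.0
        assert rr[distal].min() >= 195.0 and rr[distal].max() <= 250.0

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            band_rois((50.0, 50.0), onh_radius_px=30.0, lateral_scale_um=5.0,
                      shape=(101, 101), band_um=55.0, fov_radius_um=250.0)

    def test_radial_gradient_thickens_distal_band(self):
        """Phantom truth: outward-growing retina reads thicker distally."""
        cfg = ot.study_config(seed=4, radial_thickness_gradient_um=30.0)
        _, truth = ot.make_phantom(cfg)
        scale = cfg.axial_scale_tissue_um
        total = truth.layer_thickness_um("vitreous_NFL", "RPE_posterior", scale)
        adjacent, distal = band_rois(
            cfg.onh_center_xy, cfg.onh_radius_px, cfg.lateral_scale_um,
            total.shape, band_um=55.0,
        )
        adj, dist, diff = band_difference(total, adjacent, distal)
        assert diff > 0

    def test_flat_phantom_zero_difference(self, noise_free):
        _, truth = noise_free
        total = truth.layer_thickness_um("vitreous_NFL", "RPE_posterior",
                                         3.42 / 1.35)
        adjacent, distal = band_rois((31.5, 63.5), 8.0, 6.25, total.shape,
                                     band_um=55.0)
        adj, dist, diff = band_difference(total, adjacent, distal)
        assert abs(diff) < 0.5

    def test_gradient_difference_matches_truth_profile(self):
        """Analytic oracle: difference equals the truth-map band contrast."""
        cfg = ot.study_config(seed=4, radial_thickness_gradient_um=30.0)
        vol, truth = ot.make_phantom(cfg)
        seg = ot.segment_retina(vol)
        scale = vol.axial_scale_um
        total = ot.thickness_map(seg, "vitreous_NFL", "RPE_posterior", scale)
        true_total = truth.layer_thickness_um("vitreous_NFL", "RPE_posterior", scale)
        adjacent, distal = band_rois(
            cfg.onh_center_xy, cfg.onh_radius_px, cfg.lateral_scale_um,
            total.shape, band_um=55.0, exclusions=truth.onh_mask,
        )
        _, _, got = band_difference(total, adjacent, distal)
        _, _, expected = band_difference(true_total, adjacent, distal)
        assert abs(got - expected) <= 2.0

    def test_empty_band_rejected(self):
        total = np.full((50, 50), np.nan)
        adjacent = np.zeros((50, 50), bool)
        adjacent[20, 20] = True
        distal = np.zeros_like(adjacent)
        distal[5, 5] = True
        with pytest.raises(ValueError):
            band_difference(total, adjacent, distal)


class TestThicknessTable:
    def test_five_layers_per_roi_and_conservation(self, study_seg):
        seg, _ = study_seg
        roi = select_roi(np.zeros_like(seg.onh.mask), seg.onh.mask, 51.0, 6.25)
        table = thickness_table(seg, 2.53, {"roi0": roi}, "s1", "P14")
        assert len(table) == 5
        assert set(table["layer"]) == {"NFL", "IPL", "INL", "ORL", "total"}
        by_layer = table.set_index("layer")["thickness_um"]
        assert (table["thickness_um"] > 0).all()
        assert abs(by_layer[["NFL", "IPL", "INL", "ORL"]].sum()
                   - by_layer["total"]) < 1e-6

    def test_unknown_age_rejected(self, study_seg):
        seg, _ = study_seg
        roi = select_roi(np.zeros_like(seg.onh.mask), seg.onh.mask, 51.0, 6.25)
        with pytest.raises(ValueError, match="age_label"):
            thickness_table(seg, 2.53, {"r": roi}, "s1", "P99")
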