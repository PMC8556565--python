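"""Layer-thickness morphometry.

Converts boundary surfaces to micrometre thickness maps, selects
cylindrical regions of interest (ROIs) that avoid major vessels and the
ONH, and measures concentric bands adjacent and distal to the ONH.

Layer definitions (boundary pairs, anterior to posterior):

====== =============================
layer  boundaries
====== =============================
NFL    vitreous_NFL  -> NFL_IPL
IPL    NFL_IPL       -> IPL_INL
INL    IPL_INL       -> OPL
ORL    OPL           -> RPE_posterior
total  vitreous_NFL  -> RPE_posterior
====== =============================

so the four layers partition the total retina exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import BOUNDARY_NAMES, SegmentationResult

__all__ = [
    "LAYER_DEFINITIONS",
    "RoiSpec",
    "axial_scale",
    "thickness_map",
    "select_roi",
    "roi_thickness",
    "band_rois",
    "band_difference",
    "thickness_table",
]

LAYER_DEFINITIONS: dict[str, tuple[str, str]] = {
    "NFL": ("vitreous_NFL", "NFL_IPL"),
    "IPL": ("NFL_IPL", "IPL_INL"),
    "INL": ("IPL_INL", "OPL"),
    "ORL": ("OPL", "RPE_posterior"),
    "total": ("vitreous_NFL", "RPE_posterior"),
}

AGE_LABELS = ("P7", "P10", "P12", "P14", "P17", "P21")


def axial_scale(native_um_per_px_air: float, refractive_index: float) -> float:
    """Axial pixel size in tissue: the in-air sampling divided by the index.

    With the native 3.42 um/pixel in air and a tissue refractive index of
    1.35 this gives 2.53 um/pixel.
    """
    if native_um_per_px_air <= 0 or refractive_index <= 0:
        raise ValueError("scale and refractive index must be positive")
    return native_um_per_px_air / refractive_index


def thickness_map(
    seg: SegmentationResult, upper: str, lower: str, scale_um: float
) -> np.ndarray:
    """Thickness (um) between two boundaries: (lower - upper) * scale.

    NaN boundary depths propagate into the map.
    """
    order = {n: i for i, n in enumerate(BOUNDARY_NAMES)}
    if upper not in order or lower not in order:
        raise KeyError(f"unknown boundary pair ({upper!r}, {lower!r})")
    if order[upper] >= order[lower]:
        raise ValueError(f"{upper!r} is not anterior to {lower!r}")
    up = seg.boundaries[upper].depth
    lo = seg.boundaries[lower].depth
    return (lo - up) * float(scale_um)


@dataclass
class RoiSpec:
    """Cylindrical ROI: en-face centre (pixels), radius, exclusions used."""

    center: tuple[float, float]
    radius_um: float
    radius_px: float
    excludes: tuple[str, ...] = ("vessel_mask", "onh_mask")


def _disk(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    bb, aa = np.meshgrid(
        np.arange(shape[0], dtype=float), np.arange(shape[1], dtype=float),
        indexing="ij",
    )
    return np.hypot(bb - center[0], aa - center[1]) <= radius_px


def select_roi(
    vessel_mask: np.ndarray,
    onh_mask: np.ndarray,
    radius_um: float,
    lateral_scale_um: float,
) -> RoiSpec:
    """Deterministically place a disk ROI avoiding vessels, ONH and borders.

    Among all centres whose disk is disjoint from both exclusion masks and
    fully inside the field of view, the one maximising the distance to the
    nearest excluded pixel is chosen (ties: smallest (row, col)).  With no
    exclusions at all the field-of-view centre is returned.
    """
    if radius_um <= 0 or lateral_scale_um <= 0:
        raise ValueError("radius and scale must be positive")
    vessel_mask = np.asarray(vessel_mask, bool)
    onh_mask = np.asarray(onh_mask, bool)
    excluded = vessel_mask | onh_mask
    H, W = excluded.shape
    r_px = radius_um / lateral_scale_um
    ii, jj = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    edge_dist = np.minimum.reduce([ii, jj, H - 1 - ii, W - 1 - jj])
    inside = edge_dist >= r_px
    if not inside.any():
        raise ValueError(
            f"ROI radius {radius_um} um ({r_px:.1f} px) exceeds the field of view"
        )
    if not excluded.any():
        centre = ((H - 1) / 2.0, (W - 1) / 2.0)
        return RoiSpec(center=centre, radius_um=radius_um, radius_px=r_px)
    clearance = ndimage.distance_transform_edt(~excluded)
    feasible = inside & (clearance > r_px)
    if not feasible.any():
        raise ValueError(
            "no feasible ROI centre: every candidate disk intersects the "
            "vessel/ONH exclusion masks or the field-of-view border"
        )
    score = np.where(feasible, clearance, -np.inf)
    flat = int(score.argmax())  # C order -> smallest (row, col) on ties
    centre = (float(flat // W), float(flat % W))
    return RoiSpec(center=centre, radius_um=radius_um, radius_px=r_px)


def roi_thickness(thickness: np.ndarray, roi: RoiSpec) -> tuple[float, int]:
    """Mean thickness over the non-NaN pixels of the ROI disk, with count."""
    mask = _disk(thickness.shape, roi.center, roi.radius_px)
    values = thickness[mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("ROI contains no valid (non-NaN) thickness pixels")
    return float(values.mean()), int(values.size)


def band_rois(
    onh_center: tuple[float, float],
    onh_radius_px: float,
    lateral_scale_um: float,
    shape: tuple[int, int],
    band_um: float = 55.0,
    fov_radius_um: float | None = None,
    exclusions: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Concentric bands around the ONH: adjacent and distal annuli.

    The adjacent band spans ``[r_onh, r_onh + band]`` um from the ONH
    centre; the distal band ``[r_fov - band, r_fov]``, where ``r_fov``
    defaults to the distance from the ONH centre to the nearest field
    edge.  Overlapping bands raise an error (such samples are excluded
    from analysis).  Pixels in ``exclusions`` are removed from both bands.
    """
    H, W = shape
    cb, ca = onh_center
    if fov_radius_um is None:
        fov_radius_um = min(cb, ca, H - 1 - cb, W - 1 - ca) * lateral_scale_um
    r_onh_um = onh_radius_px * lateral_scale_um
    if r_onh_um + band_um > fov_radius_um - band_um:
        raise ValueError(
            f"adjacent band (ends {r_onh_um + band_um:.0f} um) overlaps the "
            f"distal band (starts {fov_radius_um - band_um:.0f} um); sample "
            "must be excluded"
        )
    bb, aa = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    rr_um = np.hypot(bb - cb, aa - ca) * lateral_scale_um
    adjacent = (rr_um >= r_onh_um) & (rr_um < r_onh_um + band_um)
    distal = (rr_um >= fov_radius_um - band_um) & (rr_um <= fov_radius_um)
    if exclusions is not None:
        adjacent &= ~exclusions
        distal &= ~exclusions
    return adjacent, distal


def band_difference(
    total_map: np.ndarray, adjacent: np.ndarray, distal: np.ndarray
) -> tuple[float, float, float]:
    """Mean thickness of each band and their (distal - adjacent) difference."""
    results = []
    for name, band in (("adjacent", adjacent), ("distal", distal)):
        vals = total_map[band]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"{name} band holds no valid thickness pixels")
        results.append(float(vals.mean()))
    mean_adj, mean_dist = results
    return mean_adj, mean_dist, mean_dist - mean_adj


def thickness_table(
    seg: SegmentationResult,
    scale_um: float,
    rois: dict[str, RoiSpec],
    sample_id: str,
    age_label: str,
) -> pd.DataFrame:
    """Long-format thickness records: one row per (layer, ROI).

    Columns: sample_id, age_label, layer, roi_id, thickness_um, n_alines.
    """
    if age_label not in AGE_LABELS:
        raise ValueError(f"age_label must be one of {AGE_LABELS}")
    rows = []
    for roi_id, roi in rois.items():
        for layer, (upper, lower) in LAYER_DEFINITIONS.items():
            tmap = thickness_map(seg, upper, lower, scale_um)
            mean, n = roi_thickness(tmap, roi)
            rows.append(
                {
                    "sample_id": sample_id,
                    "age_label": age_label,
                    "layer": layer,
                    "roi_id": roi_id,
                    "thickness_um": mean,
                    "n_alines": n,
                }
            )
    return pd.DataFrame(rows)
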