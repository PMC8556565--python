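"""Semi-automatic retinal layer segmentation.

Iterative boundary detection on a denoised structural volume, driven by the
image intensity ``I`` and its axial derivative ``D``:

1. the RPE-Bruch complex is found first as the brightest band of every
   A-line;
2. the optic nerve head (ONH) is located as a disruption in an en-face
   projection of the RPE band and excluded as a cylinder;
3. the vitreous/NFL interface is the strongest dark-to-bright axial
   gradient about 200 um anterior to the RPE;
4. the OPL is a local intensity maximum selected under a squared-Hann
   axial weighting;
5. the IPL/INL interface is the strongest bright-to-dark gradient between
   the vitreous posterior region and the OPL;
6. the NFL/IPL interface is the strongest gradient under a second
   squared-Hann weighting anterior to the IPL/INL interface;
7. the photoreceptor outer-segment rise is the maximum gradient between
   the OPL and the RPE anterior edge;
8. every boundary is smoothed per B-scan by a high-order polynomial fit,
   replacing points more than ``sd_threshold`` standard deviations from
   the curve by the fitted value.

All argmax/argmin ties resolve to the anterior-most depth.  Optional
user-supplied prior depths make the pipeline semi-automatic on difficult
data; the defaults run fully automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .preprocess import average_frames
from .volume import OCTVolume

__all__ = [
    "BOUNDARY_NAMES",
    "BoundarySurface",
    "SegmentationParams",
    "SegmentationResult",
    "ONHResult",
    "SegmentationError",
    "denoise",
    "axial_derivative",
    "detect_rpe",
    "detect_onh",
    "detect_vitreous_nfl",
    "detect_opl",
    "detect_ipl_inl",
    "detect_nfl_ipl",
    "detect_os",
    "correct_boundary",
    "segment_retina",
]

BOUNDARY_NAMES = (
    "vitreous_NFL",
    "NFL_IPL",
    "IPL_INL",
    "OPL",
    "OS_anterior",
    "RPE_posterior",
)
_EXTRA_NAMES = ("RPE_center",)


class SegmentationError(RuntimeError):
    """Raised when the segmentation cannot proceed (e.g. no RPE signal)."""


@dataclass
class BoundarySurface:
    """Per-(bscan, aline) float depth map of one anatomical interface.

    Depths are in axial pixels, NaN where undetected.  ``low_confidence``
    optionally marks en-face points where the detector fell back to a prior
    or a degenerate rule.
    """

    name: str
    depth: np.ndarray
    low_confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.name not in BOUNDARY_NAMES + _EXTRA_NAMES:
            raise ValueError(f"unknown boundary name {self.name!r}")
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2:
            raise ValueError("boundary depth map must be 2-D (bscan, aline)")


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation pipeline.

    ``kernel_size`` is the (depth, lateral) extent of the rectangular
    averaging kernel; ``prior_retina_um`` the expected vitreous-to-RPE
    distance; ``hann_length_px`` the squared-Hann window length used by the
    OPL and NFL/IPL detectors; ``poly_order``/``sd_threshold`` control the
    artifact-correcting polynomial fit; ``onh_drop_fraction`` the en-face
    intensity drop (relative to the median) that defines the ONH
    disruption.
    """

    kernel_size: tuple[int, int] = (3, 11)
    kernel_bscans: int = 5
    prior_retina_um: float = 200.0
    retina_margin_um: float = 75.0
    hann_length_px: int = 31
    poly_order: int = 4
    sd_threshold: float = 2.0
    onh_drop_fraction: float = 0.6
    rpe_band_halfwidth_px: float = 3.0
    opl_depth_fraction: float = 0.5
    opl_search_fraction: float = 0.3
    nfl_prior_um: float = 18.0
    min_gradient: float = 0.0
    low_contrast_threshold: float = 0.05
    axial_scale_um: float = 3.42 / 1.35
    #: optional user-supplied prior depth maps (semi-automatic overrides)
    prior_depths: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kd, kl = self.kernel_size
        if kd < 1 or kl < 1 or kd % 2 == 0 or kl % 2 == 0:
            raise ValueError("kernel dimensions must be odd and >= 1")
        if self.kernel_bscans < 1 or self.kernel_bscans % 2 == 0:
            raise ValueError("kernel_bscans must be odd and >= 1")
        if self.poly_order < 1:
            raise ValueError("poly_order must be >= 1")
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.axial_scale_um <= 0:
            raise ValueError("axial_scale_um must be positive")


@dataclass
class ONHResult:
    """Optic-nerve-head geometry: centre, equivalent-circle width, mask."""

    center: tuple[float, float] | None
    width_px: float
    mask: np.ndarray


@dataclass
class SegmentationResult:
    """Ordered boundary surfaces, ONH geometry, validity mask, parameters."""

    boundaries: dict[str, BoundarySurface]
    onh: ONHResult
    valid_mask: np.ndarray
    params: SegmentationParams

    def to_dataframe(self):
        """Long-format table: (bscan, aline, boundary, depth_px)."""
        import pandas as pd

        rows = []
        for name in BOUNDARY_NAMES:
            d = self.boundaries[name].depth
            B, A = d.shape
            bb, aa = np.meshgrid(np.arange(B), np.arange(A), indexing="ij")
            rows.append(
                pd.DataFrame(
                    {
                        "bscan": bb.ravel(),
                        "aline": aa.ravel(),
                        "boundary": name,
                        "depth_px": d.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------- #
# elementary operators


def denoise(vol3d: np.ndarray, kernel_size: tuple[int, int] = (3, 5)) -> np.ndarray:
    """Rectangular nearest-neighbour averaging over (depth, aline).

    Normalised box filter with reflect padding, applied independently to
    every B-scan; reduces static speckle before boundary detection.
    """
    kd, kl = kernel_size
    if kd % 2 == 0 or kl % 2 == 0 or kd < 1 or kl < 1:
        raise ValueError("kernel dimensions must be odd and >= 1")
    return ndimage.uniform_filter(
        np.asarray(vol3d, dtype=float), size=(1, kd, kl), mode="reflect"
    )


def axial_derivative(vol3d: np.ndarray) -> np.ndarray:
    """Signed axial derivative D (central differences, one-sided edges)."""
    vol3d = np.asarray(vol3d, dtype=float)
    if vol3d.shape[1] < 2:
        raise ValueError("need at least 2 depth pixels for a derivative")
    return np.gradient(vol3d, axis=1)


def _sq_hann(z: np.ndarray, center: np.ndarray, length: float) -> np.ndarray:
    """Squared Hann window of given length centred per A-line; 0 outside."""
    u = z - center
    w = 0.5 * (1.0 + np.cos(2.0 * np.pi * u / length))
    w = np.where(np.abs(u) <= length / 2.0, w, 0.0)
    return w * w


def _window_mask(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Boolean (B, Z, A) mask of depths strictly inside per-A-line bounds."""
    return (z > lo[:, None, :]) & (z < hi[:, None, :])


def _argext(values: np.ndarray, mask: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Masked per-A-line arg-extremum along depth; NaN where mask is empty.

    Ties resolve to the smallest depth (anterior).  Returns (depth_map,
    extremum_value).
    """
    fill = -np.inf if mode == "max" else np.inf
    v = np.where(mask, values, fill)
    if mode == "max":
        idx = v.argmax(axis=1)
        ext = v.max(axis=1)
    else:
        idx = v.argmin(axis=1)
        ext = v.min(axis=1)
    depth = idx.astype(float) + _parabolic_offset(v, idx)
    empty = ~mask.any(axis=1)
    depth[empty] = np.nan
    ext = np.where(empty, np.nan, ext)
    return depth, ext


def _parabolic_offset(v: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-pixel peak offset from a 3-point parabola through the extremum.

    Zero wherever a neighbour is missing (window edge) or the curvature
    vanishes; always within (-0.5, 0.5).
    """
    Z = v.shape[1]
    i0 = np.clip(idx - 1, 0, Z - 1)
    i2 = np.clip(idx + 1, 0, Z - 1)
    take = np.take_along_axis
    a = take(v, i0[:, None, :], axis=1)[:, 0, :]
    b = take(v, idx[:, None, :], axis=1)[:, 0, :]
    c = take(v, i2[:, None, :], axis=1)[:, 0, :]
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        denom = a - 2 * b + c
        ok = (
            np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
            & (np.abs(denom) > 0) & (idx > 0) & (idx < Z - 1)
        )
        delta = 0.5 * (a - c) / denom
    delta = np.where(ok & (np.abs(delta) < 0.5), delta, 0.0)
    return delta


# ---------------------------------------------------------------------- #
# boundary detectors


def detect_rpe(vol3d: np.ndarray) -> BoundarySurface:
    """RPE-Bruch band centre: the brightest voxel of every A-line.

    The RPE-Bruch complex yields the highest back-scattered intensity of
    the retina, so a per-A-line argmax on the denoised volume localises the
    band; ties resolve to the anterior-most depth.  A-lines with no
    positive signal (or all-NaN) return NaN.
    """
    v = np.asarray(vol3d, dtype=float)
    filled = np.where(np.isfinite(v), v, -np.inf)
    idx = filled.argmax(axis=1)
    peak = filled.max(axis=1)
    depth = idx.astype(float) + _parabolic_offset(filled, idx)
    depth[~np.isfinite(peak) | (peak <= 0)] = np.nan
    return BoundarySurface(name="RPE_center", depth=depth)


def _smooth_surface(depth: np.ndarray, poly_order: int, sd_threshold: float,
                    passes: int = 3) -> np.ndarray:
    """Robust per-B-scan polynomial smoothing (trim outliers, refit).

    Initial outlier trim against the B-scan median using the MAD scale
    (immune to compact outlier runs such as the ONH), then iterated
    polynomial fits trimming residuals beyond ``sd_threshold`` robust
    standard deviations.
    """
    B, A = depth.shape
    x = np.arange(A, dtype=float)
    out = np.empty_like(depth)
    for b in range(B):
        d = depth[b]
        keep = np.isfinite(d)
        if keep.sum() < poly_order + 1:
            out[b] = np.nan
            continue
        med = np.median(d[keep])
        mad_sigma = 1.4826 * np.median(np.abs(d[keep] - med))
        if mad_sigma > 0:
            trimmed = keep & (np.abs(d - med) <= max(3.0 * sd_threshold * mad_sigma, 10.0))
            if trimmed.sum() >= poly_order + 1:
                keep = trimmed
        fit = None
        for _ in range(passes):
            series = np.polynomial.Polynomial.fit(x[keep], d[keep], poly_order)
            fit = series(x)
            res = d - fit
            sd = 1.4826 * np.median(np.abs(res[keep]))
            if sd == 0:
                break
            new_keep = np.isfinite(d) & (np.abs(res) <= sd_threshold * sd)
            if new_keep.sum() < poly_order + 1 or (new_keep == keep).all():
                break
            keep = new_keep
        out[b] = fit
    # fill B-scans that had too few valid points from the nearest fitted one
    bad = ~np.isfinite(out).all(axis=1)
    if bad.any() and not bad.all():
        good = np.flatnonzero(~bad)
        for b in np.flatnonzero(bad):
            out[b] = out[good[np.argmin(np.abs(good - b))]]
    return out


def detect_onh(
    vol3d: np.ndarray, rpe: BoundarySurface, params: SegmentationParams
) -> ONHResult:
    """Locate the ONH as a disruption of the en-face RPE band projection.

    The mean intensity in a band of ``rpe_band_halfwidth_px`` around the
    (polynomial-smoothed) RPE surface is projected en face; the largest
    connected region falling below ``onh_drop_fraction`` times the median
    defines the disruption.  Its equivalent-circle diameter is the ONH
    width and the exclusion mask is that circle — the disruption is assumed
    quasi-cylindrical, with no curvature along the axial direction.
    """
    v = np.asarray(vol3d, dtype=float)
    B, Z, A = v.shape
    smoothed = _smooth_surface(rpe.depth, params.poly_order, params.sd_threshold)
    z = np.arange(Z, dtype=float)[None, :, None]
    hw = params.rpe_band_halfwidth_px
    band = np.abs(z - smoothed[:, None, :]) <= hw
    counts = band.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        enface = np.where(band, v, 0.0).sum(axis=1) / counts
    enface[counts == 0] = np.nan
    med = np.nanmedian(enface)
    low = enface < params.onh_drop_fraction * med
    if not low.any():
        return ONHResult(center=None, width_px=0.0, mask=np.zeros((B, A), bool))
    labels, n = ndimage.label(low, structure=np.ones((3, 3), int))
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    region = labels == biggest
    area = float(region.sum())
    width = 2.0 * np.sqrt(area / np.pi)
    cb, ca = ndimage.center_of_mass(region)
    bb, aa = np.meshgrid(np.arange(B, dtype=float), np.arange(A, dtype=float),
                         indexing="ij")
    mask = np.hypot(bb - cb, aa - ca) <= width / 2.0
    return ONHResult(center=(float(cb), float(ca)), width_px=float(width), mask=mask)


def detect_vitreous_nfl(
    vol3d: np.ndarray,
    D: np.ndarray,
    rpe: BoundarySurface,
    params: SegmentationParams,
) -> BoundarySurface:
    """Vitreous/NFL interface: strongest positive gradient near the prior.

    The search window is centred ``prior_retina_um`` anterior to the RPE
    band centre with a half-width of ``retina_margin_um`` (the a-priori
    vitreous-to-RPE distance); the dark-vitreous-to-bright-NFL transition
    is the maximum of D there.  A-lines whose window holds no positive
    gradient (pure vitreous) return NaN.
    """
    scale = params.axial_scale_um
    prior_px = params.prior_retina_um / scale
    margin_px = params.retina_margin_um / scale
    centre = rpe.depth - prior_px
    z = np.arange(D.shape[1], dtype=float)[None, :, None]
    mask = _window_mask(z, centre - margin_px, centre + margin_px)
    mask &= np.isfinite(rpe.depth)[:, None, :]
    depth, ext = _argext(D, mask, "max")
    depth[~(ext > params.min_gradient)] = np.nan
    return BoundarySurface(name="vitreous_NFL", depth=depth)


def detect_opl(
    vol3d: np.ndarray,
    inner_bounds: BoundarySurface,
    rpe: BoundarySurface,
    params: SegmentationParams,
) -> BoundarySurface:
    """OPL: local intensity maximum under a squared-Hann axial weighting.

    The intensity profile between the inner retina and the RPE anterior
    edge is weighted by a squared Hann window of ``hann_length_px`` centred
    at the expected OPL depth (``opl_depth_fraction`` of the local
    vitreous-to-RPE distance); the weighted argmax is the OPL.  If the
    search window is shorter than the Hann length the weighting is dropped
    (plain local maximum); windows with negligible intensity contrast are
    flagged low-confidence (the result is then dominated by the prior).
    """
    v = np.asarray(vol3d, dtype=float)
    vnfl = inner_bounds.depth
    dist = rpe.depth - vnfl
    lo = vnfl + params.opl_search_fraction * dist
    hi = rpe.depth - params.rpe_band_halfwidth_px
    expected = vnfl + params.opl_depth_fraction * dist
    if "OPL" in params.prior_depths:
        expected = np.asarray(params.prior_depths["OPL"], dtype=float)
    z = np.arange(v.shape[1], dtype=float)[None, :, None]
    mask = _window_mask(z, lo, hi)
    window_len = np.nanmedian(hi - lo)
    if np.isfinite(window_len) and window_len < params.hann_length_px:
        weight = np.ones_like(v)
    else:
        weight = _sq_hann(z, expected[:, None, :], float(params.hann_length_px))
    depth, _ = _argext(v * weight, mask, "max")
    # contrast check on the unweighted profile
    vmax = np.where(mask, v, -np.inf).max(axis=1)
    vmin = np.where(mask, v, np.inf).min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrast = (vmax - vmin) / np.where(vmax > 0, vmax, np.nan)
    low_conf = ~(contrast >= params.low_contrast_threshold) & np.isfinite(depth)
    return BoundarySurface(name="OPL", depth=depth, low_confidence=low_conf)


def detect_ipl_inl(
    vol3d: np.ndarray,
    D: np.ndarray,
    vitreous_nfl: BoundarySurface,
    opl: BoundarySurface,
    params: SegmentationParams | None = None,
) -> BoundarySurface:
    """IPL/INL interface: minimum of D between the vitreous surface and OPL.

    A hard axial gate (linear mask) on the derivative: the strongest
    bright-IPL-to-dark-INL transition in the window is the boundary.
    """
    z = np.arange(D.shape[1], dtype=float)[None, :, None]
    mask = _window_mask(z, vitreous_nfl.depth, opl.depth)
    depth, _ = _argext(D, mask, "min")
    return BoundarySurface(name="IPL_INL", depth=depth)


def detect_nfl_ipl(
    vol3d: np.ndarray,
    D: np.ndarray,
    vitreous_nfl: BoundarySurface,
    ipl_inl: BoundarySurface,
    params: SegmentationParams,
) -> BoundarySurface:
    """NFL/IPL interface: squared-Hann-weighted gradient extremum.

    |D| between the vitreous surface and the IPL/INL interface is weighted
    by a squared Hann window centred at the expected NFL posterior depth
    (``nfl_prior_um`` below the surface).  The first ``kernel_size[0]``
    pixels after the vitreous rise are excluded so the (large) surface
    gradient spread by denoising cannot shadow the layer transition.  If no
    gradient survives, the boundary collapses onto the vitreous surface
    (degenerate, zero-thickness NFL).
    """
    vnfl = vitreous_nfl.depth
    kd = params.kernel_size[0]
    expected = vnfl + params.nfl_prior_um / params.axial_scale_um
    if "NFL_IPL" in params.prior_depths:
        expected = np.asarray(params.prior_depths["NFL_IPL"], dtype=float)
    z = np.arange(D.shape[1], dtype=float)[None, :, None]
    mask = _window_mask(z, vnfl + kd, ipl_inl.depth)
    weight = _sq_hann(z, expected[:, None, :], float(params.hann_length_px))
    depth, ext = _argext(np.abs(D) * weight, mask, "max")
    collapse = ~(ext > params.min_gradient) & np.isfinite(vnfl) & np.isfinite(depth)
    depth = np.where(collapse, vnfl, depth)
    return BoundarySurface(name="NFL_IPL", depth=depth, low_confidence=collapse)


def detect_os(
    vol3d: np.ndarray,
    D: np.ndarray,
    opl: BoundarySurface,
    rpe: BoundarySurface,
    params: SegmentationParams | None = None,
) -> BoundarySurface:
    """Photoreceptor outer-segment rise: max D between OPL and RPE anterior.

    Detections landing within the denoising kernel's reach of the window's
    posterior edge are flagged low-confidence — without a distinct IS/OS
    band the detector can only find the RPE anterior rise.
    """
    params = params or SegmentationParams()
    hw = params.rpe_band_halfwidth_px
    hi = rpe.depth - hw
    z = np.arange(D.shape[1], dtype=float)[None, :, None]
    mask = _window_mask(z, opl.depth, hi)
    depth, _ = _argext(D, mask, "max")
    low_conf = np.isfinite(depth) & (hi - depth <= params.kernel_size[0])
    return BoundarySurface(name="OS_anterior", depth=depth, low_confidence=low_conf)


def correct_boundary(
    surface: BoundarySurface, params: SegmentationParams
) -> BoundarySurface:
    """Smooth a boundary with a per-B-scan high-order polynomial fit.

    A least-squares polynomial of order ``poly_order`` is fitted to
    depth(aline); points deviating from the curve by more than
    ``sd_threshold`` residual standard deviations are replaced by the
    fitted value, all others are kept, and NaNs are filled from the fit.
    B-scans with fewer than ``poly_order + 1`` valid points take the fit of
    the nearest fittable B-scan and are flagged low-confidence.
    """
    depth = surface.depth
    B, A = depth.shape
    x = np.arange(A, dtype=float)
    out = np.empty_like(depth)
    fits = np.full_like(depth, np.nan)
    fallback = np.zeros((B, A), dtype=bool)
    for b in range(B):
        d = depth[b]
        valid = np.isfinite(d)
        if valid.sum() < params.poly_order + 1:
            fallback[b] = True
            continue
        series = np.polynomial.Polynomial.fit(x[valid], d[valid], params.poly_order)
        fit = series(x)
        fits[b] = fit
        res = d - fit
        sd = np.std(res[valid])
        keep = valid & (np.abs(res) <= params.sd_threshold * sd)
        out[b] = np.where(keep, d, fit)
    deficient = np.flatnonzero(fallback[:, 0])
    if deficient.size:
        good = np.flatnonzero(~fallback[:, 0])
        if good.size == 0:
            raise SegmentationError(
                f"no B-scan of {surface.name} has enough valid points "
                f"({params.poly_order + 1}) for the polynomial fit"
            )
        for b in deficient:
            out[b] = fits[good[np.argmin(np.abs(good - b))]]
    low_conf = fallback
    if surface.low_confidence is not None:
        low_conf = low_conf | surface.low_confidence
    return BoundarySurface(name=surface.name, depth=out, low_confidence=low_conf)


# ---------------------------------------------------------------------- #
# pipeline


def _apply_onh_nan(depth: np.ndarray, onh_mask: np.ndarray) -> np.ndarray:
    d = depth.copy()
    d[onh_mask] = np.nan
    return d


def segment_retina(
    vol: OCTVolume | np.ndarray,
    params: SegmentationParams | None = None,
) -> SegmentationResult:
    """Run the full iterative segmentation on a structural volume.

    Accepts a 4-D :class:`~octretina.volume.OCTVolume` (frames are
    averaged) or a 3-D ``(bscan, depth, aline)`` array.  Executes denoise
    -> RPE -> ONH exclusion -> vitreous/NFL -> OPL -> IPL/INL -> NFL/IPL ->
    outer segments, polynomially corrects every surface, masks the ONH in
    all of them, and enforces the anterior-to-posterior ordering (violations
    are clipped with a warning).
    """
    if params is None:
        params = SegmentationParams()
    if isinstance(vol, OCTVolume):
        struct = average_frames(vol)
        if vol.axial_scale_um != params.axial_scale_um:
            params = replace(params, axial_scale_um=vol.axial_scale_um)
    else:
        struct = np.asarray(vol, dtype=float)
        if struct.ndim != 3:
            raise ValueError("expected a 3-D (bscan, depth, aline) array")

    # boundary detection runs on a volume averaged over adjacent B-scans as
    # well (boundaries vary slowly along that axis); the ONH detector gets a
    # lightly smoothed volume so lateral smear does not inflate the
    # disruption footprint.
    if params.kernel_bscans > 1:
        pre = ndimage.uniform_filter(
            np.asarray(struct, dtype=float),
            size=(params.kernel_bscans, 1, 1), mode="reflect",
        )
    else:
        pre = struct
    sm = denoise(pre, params.kernel_size)
    D = axial_derivative(sm)

    rpe_raw = detect_rpe(sm)
    nan_frac = np.mean(~np.isfinite(rpe_raw.depth))
    if nan_frac > 0.5:
        raise SegmentationError(
            f"RPE undetectable on {nan_frac:.0%} of A-lines: no usable signal"
        )
    sm_light = denoise(struct, (min(params.kernel_size[0], 3), 3))
    onh = detect_onh(sm_light, rpe_raw, params)

    def _corrected(surface: BoundarySurface) -> BoundarySurface:
        masked = BoundarySurface(
            name=surface.name,
            depth=_apply_onh_nan(surface.depth, onh.mask),
            low_confidence=surface.low_confidence,
        )
        return correct_boundary(masked, params)

    rpe = _corrected(rpe_raw)
    vnfl = _corrected(detect_vitreous_nfl(sm, D, rpe, params))
    opl = _corrected(detect_opl(sm, vnfl, rpe, params))
    ipl_inl = _corrected(detect_ipl_inl(sm, D, vnfl, opl, params))
    nfl_ipl = _corrected(detect_nfl_ipl(sm, D, vnfl, ipl_inl, params))
    os_ant = _corrected(detect_os(sm, D, opl, rpe, params))
    rpe_post = BoundarySurface(
        name="RPE_posterior",
        depth=rpe.depth + params.rpe_band_halfwidth_px,
        low_confidence=rpe.low_confidence,
    )

    ordered = [vnfl, nfl_ipl, ipl_inl, opl, os_ant, rpe_post]
    running = ordered[0].depth.copy()
    n_clipped = 0
    for surf in ordered[1:]:
        d = surf.depth
        below = d < running
        n_clipped += int(np.sum(below & np.isfinite(d) & np.isfinite(running)))
        clipped = np.where(np.isfinite(d) & np.isfinite(running),
                           np.fmax(d, running), d)
        surf.depth = clipped
        running = np.where(np.isfinite(clipped), clipped, running)
    if n_clipped:
        warnings.warn(
            f"boundary ordering violated at {n_clipped} points; clipped",
            stacklevel=2,
        )

    boundaries: dict[str, BoundarySurface] = {}
    for surf in ordered:
        surf.depth = _apply_onh_nan(surf.depth, onh.mask)
        boundaries[surf.name] = surf
    valid = np.ones_like(onh.mask, dtype=bool)
    for surf in ordered:
        valid &= np.isfinite(surf.depth)
    valid &= ~onh.mask
    return SegmentationResult(
        boundaries=boundaries, onh=onh, valid_mask=valid, params=params
    )
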