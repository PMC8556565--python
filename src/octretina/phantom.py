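"""Synthetic OCT phantom of the developing mouse retina.

Generates 4-D BM-scan volumes with a layered reflectance structure
(hyper-reflective NFL, IPL, OPL, IS/OS and RPE-Bruch bands separated by
hypo-reflective INL and ONL), multiplicative gamma speckle, depth-dependent
SNR roll-off, additive background noise, retinal vessels with dynamic
speckle and shadowing, and an optic nerve head (ONH) disruption.  Every
geometric feature is also emitted as ground truth so the preprocessing,
angiography, segmentation and morphometry stages can be tested end to end
without real acquisitions.

The default acquisition geometry follows a raster of BM-scans, each holding
several consecutive B-scans of identical A-line count, with a native axial
sampling of 3.42 um/pixel in air corrected to tissue with a refractive
index of 1.35.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .volume import OCTVolume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "VesselSpec",
    "make_phantom",
    "make_fringes",
    "make_background",
    "study_config",
    "BOUNDARY_ORDER",
]

#: Anatomical interfaces, anterior to posterior, as emitted in ground truth.
BOUNDARY_ORDER = (
    "vitreous_NFL",
    "NFL_IPL",
    "IPL_INL",
    "OPL",
    "OS_anterior",
    "RPE_posterior",
)

#: Default layer thicknesses (um).  They sum to ~200 um, the expected
#: vitreous-to-RPE distance used as segmentation prior.
DEFAULT_THICKNESSES_UM: dict[str, float] = {
    "NFL": 18.0,
    "IPL": 52.0,
    "INL": 30.0,
    "ORL": 85.0,
    "RPE_Bruch": 15.2,
}

#: Relative mean linear reflectance per region.  RPE-Bruch is the brightest
#: band; INL and ONL are hypo-reflective.
DEFAULT_REFLECTANCES: dict[str, float] = {
    "vitreous": 0.02,
    "NFL": 0.85,
    "IPL": 0.70,
    "INL": 0.30,
    "OPL": 0.65,
    "ONL": 0.25,
    "IS_OS": 0.75,
    "RPE_Bruch": 1.60,
    "below": 0.04,
}


@dataclass(frozen=True)
class VesselSpec:
    """A retinal vessel: an en-face disk with dynamic speckle and a shadow.

    ``center`` is ``(bscan, aline)`` in pixels; ``radius_px`` the en-face and
    axial half-extent; ``depth_px`` the absolute axial centre (``None`` puts
    the vessel mid-NFL, following the local surface);
    ``dynamic_variance_gain`` scales the vessel's mean intensity (fresh
    speckle is drawn every frame inside the vessel regardless).
    """

    center: tuple[float, float]
    radius_px: float
    depth_px: float | None = None
    dynamic_variance_gain: float = 1.0


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration violates its invariants."""


@dataclass
class PhantomConfig:
    """Full description of a synthetic acquisition.

    The defaults produce a vessel-free, ONH-free retina; use
    :func:`study_config` for a phantom carrying vasculature and an ONH.
    """

    n_alines: int = 128
    n_bscans: int = 64
    n_repeats: int = 5
    n_depth: int = 400
    axial_scale_air_um: float = 3.42
    refractive_index: float = 1.35
    layer_thicknesses_um: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THICKNESSES_UM)
    )
    #: np.polyval coefficients over the normalised en-face radius r in [0,1]
    #: (1 at the field corner); added to ``surface_base_px``.
    surface_curvature: tuple[float, ...] = (10.0, 0.0, 0.0)
    surface_base_px: float = 100.0
    reflectances: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFLECTANCES)
    )
    #: Gamma shape of multiplicative speckle; ``inf`` disables speckle.
    speckle_shape: float = 3.0
    #: Per-pixel signal attenuation with depth, in (0, 1].
    rolloff_decay: float = 0.9995
    #: Mean of the additive exponential background, drawn per frame.
    noise_floor: float = 0.01
    #: Width of the hyper-reflective OPL band, centred on the INL/ONL
    #: interface, and of the IS/OS band ending at the RPE anterior edge.
    opl_band_um: float = 8.0
    isos_band_um: float = 12.0
    onh_center_xy: tuple[float, float] | None = None
    onh_radius_px: float = 0.0
    #: Multiplier applied to the outer bands (IS/OS + RPE) inside the ONH.
    onh_suppression: float = 0.15
    vessel_specs: tuple[VesselSpec, ...] = ()
    shadow_attenuation: float = 0.5
    #: Field-of-view width in mm (sets the lateral scale); the imaged field
    #: is a circle of roughly 0.4 mm radius around the ONH.
    fov_width_mm: float = 0.8
    #: Increase of the total retinal thickness (um) from the field centre
    #: (normalised radius 0) to the corner (radius 1), distributed across
    #: layers proportionally to their thickness; 0 gives a uniform retina.
    radial_thickness_gradient_um: float = 0.0
    seed: int = 0

    # ------------------------------------------------------------------ #

    @property
    def axial_scale_tissue_um(self) -> float:
        return self.axial_scale_air_um / self.refractive_index

    @property
    def lateral_scale_um(self) -> float:
        return self.fov_width_mm * 1000.0 / self.n_alines

    def validate(self) -> None:
        t = self.layer_thicknesses_um
        required = {"NFL", "IPL", "INL", "ORL", "RPE_Bruch"}
        if not required.issubset(t):
            raise PhantomConfigError(f"layer_thicknesses_um must contain {required}")
        if any(v <= 0 for v in t.values()):
            raise PhantomConfigError("all layer thicknesses must be positive")
        r = self.reflectances
        others = [v for k, v in r.items() if k != "RPE_Bruch"]
        if not all(r["RPE_Bruch"] > v for v in others):
            raise PhantomConfigError(
                "RPE_Bruch must have the strictly greatest reflectance"
            )
        if not (r["INL"] < r["IPL"] and r["ONL"] < r["IPL"]):
            raise PhantomConfigError("INL and ONL must be darker than the IPL")
        if self.n_repeats < 2:
            raise PhantomConfigError("n_repeats must be >= 2 for speckle variance")
        if not (0.0 < self.rolloff_decay <= 1.0):
            raise PhantomConfigError("rolloff_decay must be in (0, 1]")
        if self.speckle_shape <= 0:
            raise PhantomConfigError("speckle_shape must be positive (inf allowed)")
        retina_px = (
            sum(t.values()) + max(self.radial_thickness_gradient_um, 0.0)
        ) / self.axial_scale_tissue_um
        if self.surface_base_px + retina_px >= self.n_depth:
            raise PhantomConfigError(
                "configured layer thicknesses exceed the axial raster: "
                f"surface at {self.surface_base_px} px + retina {retina_px:.1f} px "
                f">= n_depth {self.n_depth}"
            )

    def noise_free(self) -> "PhantomConfig":
        """A copy with speckle and background disabled (ideal reflectance)."""
        return replace(self, speckle_shape=math.inf, noise_floor=0.0)


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a phantom volume.

    ``boundaries`` maps each interface name (see :data:`BOUNDARY_ORDER`) to a
    float depth map of shape ``(n_bscans, n_alines)``; ``vessel_mask`` and
    ``onh_mask`` are binary en-face maps on the same grid.
    """

    boundaries: dict[str, np.ndarray]
    vessel_mask: np.ndarray
    onh_mask: np.ndarray
    onh_width_px: float

    def layer_thickness_um(self, upper: str, lower: str, scale_um: float) -> np.ndarray:
        return (self.boundaries[lower] - self.boundaries[upper]) * scale_um


def study_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Phantom emulating the study conditions at test scale.

    A 64 x 128 en-face raster with 5 repeated frames and 400 depth pixels,
    three major NFL vessels radiating from the field centre region, and a
    10-px-radius ONH at the field centre.
    """
    cfg = PhantomConfig(seed=seed, **overrides)
    B, A = cfg.n_bscans, cfg.n_alines
    if cfg.onh_center_xy is None:
        cfg.onh_center_xy = ((B - 1) / 2.0, (A - 1) / 2.0)
        cfg.onh_radius_px = min(10.0, B / 6.0, A / 6.0)
    if not cfg.vessel_specs:
        cfg.vessel_specs = (
            VesselSpec(center=(B * 0.25, A * 0.25), radius_px=4.0),
            VesselSpec(center=(B * 0.72, A * 0.75), radius_px=4.0),
            VesselSpec(center=(B * 0.19, A * 0.78), radius_px=5.0),
        )
    return cfg


# ---------------------------------------------------------------------- #
# geometry


def _enface_grids(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bb, aa = np.meshgrid(
        np.arange(cfg.n_bscans, dtype=float),
        np.arange(cfg.n_alines, dtype=float),
        indexing="ij",
    )
    cb = (cfg.n_bscans - 1) / 2.0
    ca = (cfg.n_alines - 1) / 2.0
    # normalised radius: 0 at field centre, 1 at the corner
    r = np.hypot((bb - cb) / max(cb, 1.0), (aa - ca) / max(ca, 1.0)) / math.sqrt(2.0)
    return bb, aa, r


def _boundary_maps(cfg: PhantomConfig) -> dict[str, np.ndarray]:
    """Float depth (px) of every interface on the en-face grid."""
    _, _, r = _enface_grids(cfg)
    scale = cfg.axial_scale_tissue_um
    total_um = sum(cfg.layer_thicknesses_um.values())
    # radial thickness gradient: every layer scaled by the same factor
    factor = 1.0 + cfg.radial_thickness_gradient_um * r / total_um
    t = {k: v / scale * factor for k, v in cfg.layer_thicknesses_um.items()}
    vnfl = cfg.surface_base_px + np.polyval(cfg.surface_curvature, r)
    nfl_ipl = vnfl + t["NFL"]
    ipl_inl = nfl_ipl + t["IPL"]
    opl = ipl_inl + t["INL"]
    rpe_ant = opl + t["ORL"]
    rpe_post = rpe_ant + t["RPE_Bruch"]
    os_ant = rpe_ant - cfg.isos_band_um / scale
    return {
        "vitreous_NFL": vnfl,
        "NFL_IPL": nfl_ipl,
        "IPL_INL": ipl_inl,
        "OPL": opl,
        "OS_anterior": os_ant,
        "RPE_posterior": rpe_post,
        "_RPE_anterior": rpe_ant,
    }


def _disk_mask(cfg: PhantomConfig, center: tuple[float, float], radius: float) -> np.ndarray:
    bb, aa, _ = _enface_grids(cfg)
    return np.hypot(bb - center[0], aa - center[1]) <= radius


def _reflectance_volume(
    cfg: PhantomConfig, bounds: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free reflectance raster plus vessel voxel mask and en-face masks."""
    B, A, Z = cfg.n_bscans, cfg.n_alines, cfg.n_depth
    z = np.arange(Z, dtype=float)[None, :, None]
    refl = np.full((B, Z, A), cfg.reflectances["vitreous"])

    def bmap(name: str) -> np.ndarray:
        return bounds[name][:, None, :]

    r = cfg.reflectances
    scale = cfg.axial_scale_tissue_um
    refl[z >= bmap("vitreous_NFL")] = r["NFL"]
    refl[z >= bmap("NFL_IPL")] = r["IPL"]
    refl[z >= bmap("IPL_INL")] = r["INL"]
    half_opl = 0.5 * cfg.opl_band_um / scale
    refl[z >= bmap("OPL") - half_opl] = r["OPL"]
    refl[z >= bmap("OPL") + half_opl] = r["ONL"]
    refl[z >= bmap("OS_anterior")] = r["IS_OS"]

    # RPE-Bruch band: raised-cosine axial profile peaking at the band centre
    # so the brightest voxel of every A-line sits at the band centre.
    rpe_ant = bmap("_RPE_anterior")
    rpe_post = bmap("RPE_posterior")
    in_band = (z >= rpe_ant) & (z < rpe_post)
    width = rpe_post - rpe_ant
    centre = 0.5 * (rpe_ant + rpe_post)
    cosine = 0.5 * (1.0 + np.cos(2.0 * np.pi * (z - centre) / width))
    band_profile = r["IS_OS"] + (r["RPE_Bruch"] - r["IS_OS"]) * cosine
    refl = np.where(in_band, band_profile, refl)
    refl[z >= rpe_post] = r["below"]

    # ONH: quasi-cylindrical suppression of the outer bands (no curvature
    # along the axial direction of the disruption).
    onh_mask = np.zeros((B, A), dtype=bool)
    if cfg.onh_center_xy is not None and cfg.onh_radius_px > 0:
        onh_mask = _disk_mask(cfg, cfg.onh_center_xy, cfg.onh_radius_px)
        outer = np.broadcast_to(z >= bmap("OS_anterior"), refl.shape)
        col = onh_mask[:, None, :] & outer
        refl[col] *= cfg.onh_suppression

    # vessels: en-face disks at NFL depth; dynamic voxels plus a shadow
    # attenuating everything beneath the vessel.
    vessel_vox = np.zeros((B, Z, A), dtype=bool)
    vessel_mask = np.zeros((B, A), dtype=bool)
    for spec in cfg.vessel_specs:
        disk = _disk_mask(cfg, spec.center, spec.radius_px)
        vessel_mask |= disk
        if spec.depth_px is None:
            depth = bounds["vitreous_NFL"] + 0.5 * (
                bounds["NFL_IPL"] - bounds["vitreous_NFL"]
            )
        else:
            depth = np.full((B, A), float(spec.depth_px))
        axial = np.abs(z - depth[:, None, :]) <= spec.radius_px
        vox = disk[:, None, :] & axial
        vessel_vox |= vox
        if spec.dynamic_variance_gain != 1.0:
            refl[vox] *= spec.dynamic_variance_gain
        shadow = disk[:, None, :] & (z > (depth + spec.radius_px)[:, None, :])
        refl[shadow] *= cfg.shadow_attenuation

    return refl, vessel_vox, np.stack([vessel_mask, onh_mask])


# ---------------------------------------------------------------------- #
# operations


def make_phantom(config: PhantomConfig) -> tuple[OCTVolume, PhantomTruth]:
    """Generate a synthetic BM-scan volume and its ground truth.

    Static tissue shares a single multiplicative speckle draw across the
    repeated frames (speckle is frozen in the absence of motion), while
    voxels inside vessels receive an independent draw per frame; every frame
    additionally receives independent exponential background noise.  The
    noise-free signal is ``reflectance * rolloff_decay**depth``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bounds = _boundary_maps(config)
    refl, vessel_vox, masks = _reflectance_volume(config, bounds)
    vessel_mask, onh_mask = masks[0].astype(bool), masks[1].astype(bool)

    B, A, Z, R = config.n_bscans, config.n_alines, config.n_depth, config.n_repeats
    z = np.arange(Z, dtype=float)[None, :, None]
    signal = refl * config.rolloff_decay**z

    shape = config.speckle_shape
    speckled = math.isfinite(shape)
    if speckled:
        g_static = rng.gamma(shape, 1.0 / shape, size=(B, Z, A))
    data = np.empty((B, R, Z, A))
    any_vessel = bool(vessel_vox.any())
    for t in range(R):
        if speckled:
            g = g_static
            if any_vessel:
                g_dyn = rng.gamma(shape, 1.0 / shape, size=(B, Z, A))
                g = np.where(vessel_vox, g_dyn, g_static)
            frame = signal * g
        else:
            frame = signal.copy()
        if config.noise_floor > 0:
            frame = frame + rng.exponential(config.noise_floor, size=(B, Z, A))
        data[:, t] = frame

    vol = OCTVolume(
        data=data,
        axial_scale_um=config.axial_scale_tissue_um,
        lateral_scale_um=config.lateral_scale_um,
        meta={"seed": config.seed, "kind": "phantom"},
    )
    truth = PhantomTruth(
        boundaries={k: bounds[k] for k in BOUNDARY_ORDER},
        vessel_mask=vessel_mask,
        onh_mask=onh_mask,
        onh_width_px=2.0 * config.onh_radius_px,
    )
    return vol, truth


def make_fringes(
    depths_px: Sequence[float],
    n_samples: int,
    a2: float = 0.0,
    a3: float = 0.0,
    k0_index: float | None = None,
    amplitudes: Sequence[float] | None = None,
) -> np.ndarray:
    """Complex spectral interferogram of point reflectors, with dispersion.

    The undispersed spectrum of a reflector at depth ``d`` is
    ``exp(2j*pi*k*d/N)`` over sample index ``k``; its depth transform (FFT)
    peaks at index ``d``.  A dispersive phase
    ``exp(1j*(a2*(k-k0)**2 + a3*(k-k0)**3))`` broadens that peak, emulating
    the chromatic mismatch a real interferometer acquires through the eye.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    depths = np.asarray(depths_px, dtype=float)
    if depths.size == 0:
        raise ValueError("at least one reflector depth is required")
    if np.any(depths < 0) or np.any(depths > n_samples / 2):
        raise ValueError("reflector depths must lie within the Nyquist range "
                         f"[0, {n_samples / 2}]")
    amps = np.ones_like(depths) if amplitudes is None else np.asarray(amplitudes, float)
    k = np.arange(n_samples, dtype=float)
    spectrum = (amps[:, None] * np.exp(2j * np.pi * np.outer(depths, k) / n_samples)).sum(axis=0)
    k0 = (n_samples - 1) / 2.0 if k0_index is None else float(k0_index)
    dk = k - k0
    spectrum = spectrum * np.exp(1j * (a2 * dk**2 + a3 * dk**3))
    return spectrum


def make_background(config: PhantomConfig) -> OCTVolume:
    """Background volume acquired outside the field of view: pure noise.

    Exponentially distributed intensities with mean ``config.noise_floor``
    on the full acquisition raster.
    """
    rng = np.random.default_rng(config.seed + 1)
    shape = (config.n_bscans, config.n_repeats, config.n_depth, config.n_alines)
    if config.noise_floor == 0:
        data = np.zeros(shape)
    elif config.noise_floor < 0:
        raise PhantomConfigError("noise_floor must be nonnegative")
    else:
        data = rng.exponential(config.noise_floor, size=shape)
    return OCTVolume(
        data=data,
        axial_scale_um=config.axial_scale_tissue_um,
        lateral_scale_um=config.lateral_scale_um,
        meta={"seed": config.seed, "kind": "background"},
    )
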