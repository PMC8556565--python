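"""Schema-validated pipeline configuration.

A :class:`PipelineConfig` collects every stage's parameters plus stage
toggles, the seed and the output directory.  Unknown keys are rejected.
Files may be TOML or YAML.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .phantom import PhantomConfig, VesselSpec
from .segmentation import SegmentationParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Strict):
    n_alines: int = 128
    n_bscans: int = 64
    n_repeats: int = 5
    n_depth: int = 400
    axial_scale_air_um: float = 3.42
    refractive_index: float = 1.35
    speckle_shape: float = 3.0
    rolloff_decay: float = 0.9995
    noise_floor: float = 0.01
    fov_width_mm: float = 0.8
    with_onh: bool = True
    with_vessels: bool = True
    onh_radius_px: float = 10.0

    def build(self, seed: int) -> PhantomConfig:
        cfg = PhantomConfig(
            n_alines=self.n_alines,
            n_bscans=self.n_bscans,
            n_repeats=self.n_repeats,
            n_depth=self.n_depth,
            axial_scale_air_um=self.axial_scale_air_um,
            refractive_index=self.refractive_index,
            speckle_shape=self.speckle_shape,
            rolloff_decay=self.rolloff_decay,
            noise_floor=self.noise_floor,
            fov_width_mm=self.fov_width_mm,
            seed=seed,
        )
        if self.with_onh:
            cfg.onh_center_xy = ((self.n_bscans - 1) / 2.0, (self.n_alines - 1) / 2.0)
            cfg.onh_radius_px = self.onh_radius_px
        if self.with_vessels:
            cfg.vessel_specs = (
                VesselSpec(center=(self.n_bscans * 0.25, self.n_alines * 0.25),
                           radius_px=4.0),
                VesselSpec(center=(self.n_bscans * 0.72, self.n_alines * 0.75),
                           radius_px=4.0),
                VesselSpec(center=(self.n_bscans * 0.19, self.n_alines * 0.78),
                           radius_px=5.0),
            )
        return cfg


class SegmentationSection(_Strict):
    kernel_depth: int = 3
    kernel_lateral: int = 5
    prior_retina_um: float = 200.0
    hann_length_px: int = 31
    poly_order: int = 4
    sd_threshold: float = 2.0
    onh_drop_fraction: float = 0.6
    rpe_band_halfwidth_px: float = 3.0

    def build(self) -> SegmentationParams:
        return SegmentationParams(
            kernel_size=(self.kernel_depth, self.kernel_lateral),
            prior_retina_um=self.prior_retina_um,
            hann_length_px=self.hann_length_px,
            poly_order=self.poly_order,
            sd_threshold=self.sd_threshold,
            onh_drop_fraction=self.onh_drop_fraction,
            rpe_band_halfwidth_px=self.rpe_band_halfwidth_px,
        )


class MorphometrySection(_Strict):
    roi_radius_um: float = 51.0
    band_um: float = 55.0
    n_rois: int = 1
    #: fail (rather than skip with a warning) when the adjacent and distal
    #: ONH bands overlap — the sample would be excluded from band analysis
    require_bands: bool = False


class StagesSection(_Strict):
    simulate: bool = True
    preprocess: bool = True
    angio: bool = True
    segment: bool = True
    quantify: bool = True
    stats: bool = True


class PipelineConfig(_Strict):
    """Top-level configuration for the end-to-end workflow."""

    seed: int = 0
    out_dir: str = "octretina_out"
    sample_id: str = "phantom-01"
    age_label: str = "P14"
    log_level: str = "INFO"
    stages: StagesSection = Field(default_factory=StagesSection)
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    segmentation: SegmentationSection = Field(default_factory=SegmentationSection)
    morphometry: MorphometrySection = Field(default_factory=MorphometrySection)

    def config_hash(self) -> str:
        """Stable hash of the scientific configuration (housekeeping fields
        like the output directory and log level excluded), stamped on every
        artifact."""
        payload = self.model_dump(exclude={"out_dir", "log_level"})
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Load a TOML/YAML config file (or defaults) with keyword overrides."""
    data: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".toml":
            data = tomllib.loads(text)
        elif path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text) or {}
        else:
            raise ValueError(f"unsupported config format {path.suffix!r}")
    data.update(overrides)
    return PipelineConfig.model_validate(data)
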