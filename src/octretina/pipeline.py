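"""End-to-end orchestration: simulate -> preprocess -> angiography ->
segmentation -> morphometry -> statistics.

Every run writes its artifacts into one output directory together with a
``run_meta.json`` recording the configuration, its hash and per-stage
timings; the hash is also stamped into HDF5 volume metadata so any
artifact can be traced to the exact configuration that produced it.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import angiography, io, morphometry, phantom, preprocess, segmentation
from .config import PipelineConfig

log = logging.getLogger("octretina")

__all__ = ["run_pipeline"]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Raises on the first stage failure.  Re-running with the same
    configuration (same seed) reproduces every artifact bit for bit.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta: dict = {"config": config.model_dump(), "config_hash": chash, "stages": {}}
    timings: dict[str, float] = {}

    def _stage(name: str):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()

    def _done(name: str):
        timings[name] = time.perf_counter() - timings[name]
        meta["stages"][name] = {"seconds": round(timings[name], 3)}

    vol = truth = None
    if config.stages.simulate:
        _stage("simulate")
        pcfg = config.phantom.build(config.seed)
        vol, truth = phantom.make_phantom(pcfg)
        vol.meta["config_hash"] = chash
        io.write_volume(vol, out / "volume.h5")
        bg = phantom.make_background(pcfg)
        io.write_volume(bg, out / "background.h5")
        _truth_to_csv(truth, out / "truth_boundaries.csv")
        io.write_mask_tiff(truth.vessel_mask, out / "truth_vessel_mask.tif")
        io.write_mask_tiff(truth.onh_mask, out / "truth_onh_mask.tif")
        _done("simulate")
    else:
        vol = io.read_volume(out / "volume.h5")

    if config.stages.preprocess:
        _stage("preprocess")
        bg_path = out / "background.h5"
        if bg_path.exists():
            vol = preprocess.subtract_background(vol, io.read_volume(bg_path))
        vol = preprocess.correct_rolloff(vol, config.phantom.rolloff_decay)
        reg = preprocess.register_bscans(vol)
        vol = reg.registered
        pd.DataFrame(reg.shifts, columns=["dz_px", "dx_px"]).to_csv(
            out / "registration_shifts.csv", index_label="bscan"
        )
        vol.meta["config_hash"] = chash
        io.write_volume(vol, out / "volume_preprocessed.h5")
        _done("preprocess")

    angio = None
    if config.stages.angio:
        _stage("angio")
        angio = angiography.motion_robust_variance(vol)
        np.save(out / "angio_variance.npy", angio.variance)
        _done("angio")

    seg = None
    if config.stages.segment:
        _stage("segment")
        params = config.segmentation.build()
        seg = segmentation.segment_retina(vol, params)
        df = seg.to_dataframe()
        df.to_csv(out / "segmentation.csv", index=False)
        sidecar = {
            "config_hash": chash,
            "onh_center": seg.onh.center,
            "onh_width_px": seg.onh.width_px,
            "n_valid_alines": int(seg.valid_mask.sum()),
        }
        (out / "segmentation.json").write_text(json.dumps(sidecar, indent=1))
        _done("segment")

    table = None
    if config.stages.quantify:
        _stage("quantify")
        if seg is None:
            raise RuntimeError("quantify stage requires the segment stage")
        scale = vol.axial_scale_um
        lateral = vol.lateral_scale_um
        # vessel mask from angiography over the inner retina
        if angio is not None:
            vd = seg.boundaries["vitreous_NFL"].depth
            od = seg.boundaries["OPL"].depth
            z0 = int(np.nanmin(vd)) if np.isfinite(vd).any() else 0
            z1 = int(np.nanmax(od)) + 1 if np.isfinite(od).any() else angio.variance.shape[1]
            enface = angiography.enface_projection(angio.variance, (z0, z1))
            vmask = angiography.vessel_mask(enface).mask
            io.write_mask_tiff(vmask, out / "vessel_mask.tif")
        else:
            vmask = np.zeros_like(seg.onh.mask)
        rois = {}
        for i in range(config.morphometry.n_rois):
            roi = morphometry.select_roi(
                vmask, seg.onh.mask, config.morphometry.roi_radius_um, lateral
            )
            rois[f"roi{i}"] = roi
        table = morphometry.thickness_table(
            seg, scale, rois, config.sample_id, config.age_label
        )
        table["config_hash"] = chash
        table.to_csv(out / "thickness.csv", index=False)
        if seg.onh.center is not None and seg.onh.width_px > 0:
            try:
                adjacent, distal = morphometry.band_rois(
                    seg.onh.center, seg.onh.width_px / 2.0, lateral,
                    seg.onh.mask.shape, band_um=config.morphometry.band_um,
                    exclusions=vmask | seg.onh.mask,
                )
                total = morphometry.thickness_map(
                    seg, "vitreous_NFL", "RPE_posterior", scale
                )
                adj, dist, diff = morphometry.band_difference(total, adjacent, distal)
                (out / "bands.json").write_text(json.dumps(
                    {"mean_adjacent_um": adj, "mean_distal_um": dist,
                     "difference_um": diff, "config_hash": chash}, indent=1))
            except ValueError as exc:
                if config.morphometry.require_bands:
                    raise
                log.warning("band analysis skipped: %s", exc)
        _done("quantify")

    if config.stages.stats and table is not None:
        _stage("stats")
        from .stats import summarize_groups

        summaries = summarize_groups(table)
        pd.DataFrame(
            [
                {
                    "age_label": s.group[0],
                    "layer": s.group[1],
                    "n": s.n,
                    "mean": s.mean,
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                    "n_outliers": len(s.outliers),
                    "config_hash": chash,
                }
                for s in summaries
            ]
        ).to_csv(out / "summary.csv", index=False)
        _done("stats")

    (out / "run_meta.json").write_text(json.dumps(meta, indent=1, default=str))
    return out


def _truth_to_csv(truth: phantom.PhantomTruth, path: Path) -> None:
    rows = []
    for name, depth in truth.boundaries.items():
        B, A = depth.shape
        bb, aa = np.meshgrid(np.arange(B), np.arange(A), indexing="ij")
        rows.append(pd.DataFrame({
            "bscan": bb.ravel(), "aline": aa.ravel(),
            "boundary_name": name, "depth_px": depth.ravel(),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
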