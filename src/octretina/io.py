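"""Reading and writing volumes, masks and tables.

HDF5 is the canonical container for 4-D volumes (dataset ``volume`` with
pixel-scale attributes); multi-page TIFF import/export is provided for
interoperability, with one page per (bscan, repeat) B-scan and a JSON
sidecar carrying shape and scale metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .volume import OCTVolume

__all__ = [
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "write_mask_tiff",
    "read_mask_tiff",
]

_REQUIRED_ATTRS = ("axial_scale_um", "lateral_scale_um")


class VolumeIOError(IOError):
    """Raised for missing metadata or unreadable volume files."""


def write_volume(vol: OCTVolume, path: str | Path) -> Path:
    """Write a volume to HDF5 (.h5/.hdf5) or multi-page TIFF (.tif/.tiff).

    TIFF export flattens the (bscan, repeat) axes into pages and stores
    shape/scale metadata in a ``<path>.json`` sidecar.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=vol.data)
            ds.attrs["axial_scale_um"] = vol.axial_scale_um
            ds.attrs["lateral_scale_um"] = vol.lateral_scale_um
            for k, v in vol.meta.items():
                if isinstance(v, (int, float, str, bool)):
                    ds.attrs[f"meta_{k}"] = v
    elif path.suffix in (".tif", ".tiff"):
        B, R, Z, A = vol.shape
        pages = vol.data.reshape(B * R, Z, A).astype(np.float32)
        tifffile.imwrite(path, pages)
        sidecar = {
            "n_bscans": B,
            "n_repeats": R,
            "n_depth": Z,
            "n_alines": A,
            "axial_scale_um": vol.axial_scale_um,
            "lateral_scale_um": vol.lateral_scale_um,
            "meta": {k: v for k, v in vol.meta.items()
                     if isinstance(v, (int, float, str, bool))},
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise VolumeIOError(f"unsupported volume format {path.suffix!r}")
    return path


def read_volume(path: str | Path) -> OCTVolume:
    """Read a volume written by :func:`write_volume`.

    HDF5 round-trips are lossless.  A TIFF stack requires its JSON sidecar
    to recover the (bscan, repeat) page factorisation and the pixel scales;
    missing scale attributes raise an error naming the attribute.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    if path.suffix in (".h5", ".hdf5"):
        try:
            with h5py.File(path, "r") as f:
                if "volume" not in f:
                    raise VolumeIOError(f"{path}: missing dataset 'volume'")
                ds = f["volume"]
                for attr in _REQUIRED_ATTRS:
                    if attr not in ds.attrs:
                        raise VolumeIOError(f"{path}: missing attribute {attr!r}")
                meta = {
                    k[len("meta_"):]: (v.item() if hasattr(v, "item") else v)
                    for k, v in ds.attrs.items() if k.startswith("meta_")
                }
                return OCTVolume(
                    data=ds[()],
                    axial_scale_um=float(ds.attrs["axial_scale_um"]),
                    lateral_scale_um=float(ds.attrs["lateral_scale_um"]),
                    meta=meta,
                )
        except OSError as exc:
            raise VolumeIOError(f"cannot parse {path} as HDF5: {exc}") from exc
    if path.suffix in (".tif", ".tiff"):
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise VolumeIOError(f"{path}: missing metadata sidecar {sidecar_path}")
        sidecar = json.loads(sidecar_path.read_text())
        for attr in _REQUIRED_ATTRS:
            if attr not in sidecar:
                raise VolumeIOError(f"{sidecar_path}: missing attribute {attr!r}")
        try:
            pages = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - tifffile raises various types
            raise VolumeIOError(f"cannot parse {path} as TIFF: {exc}") from exc
        B, R = sidecar["n_bscans"], sidecar["n_repeats"]
        pages = np.atleast_3d(pages)
        if pages.ndim == 3 and pages.shape[0] != B * R:
            raise VolumeIOError(
                f"{path}: {pages.shape[0]} pages, expected "
                f"n_bscans*n_repeats = {B * R}"
            )
        data = pages.reshape(B, R, sidecar["n_depth"], sidecar["n_alines"])
        return OCTVolume(
            data=np.asarray(data, dtype=float),
            axial_scale_um=float(sidecar["axial_scale_um"]),
            lateral_scale_um=float(sidecar["lateral_scale_um"]),
            meta=dict(sidecar.get("meta", {})),
        )
    raise VolumeIOError(f"unsupported volume format {path.suffix!r}")


def write_mask_tiff(mask: np.ndarray, path: str | Path) -> Path:
    """Write a 2-D map (boolean or float) as a single-page TIFF."""
    path = Path(path)
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)
    return path


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))
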