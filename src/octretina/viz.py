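"""Overlay rendering of segmented boundaries on B-scans."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .segmentation import BOUNDARY_NAMES, SegmentationResult

_COLORS = {
    "vitreous_NFL": "tab:blue",
    "NFL_IPL": "tab:orange",
    "IPL_INL": "gold",
    "OPL": "magenta",
    "OS_anterior": "tab:green",
    "RPE_posterior": "tab:red",
}


def render_bscan_overlay(
    struct: np.ndarray,
    seg: SegmentationResult,
    bscan: int,
    path: str | Path,
) -> Path:
    """Save one B-scan (depth x aline) with its boundary curves overlaid.

    ``struct`` is a 3-D structural volume ``(bscan, depth, aline)``; the
    image is log-compressed for display.
    """
    path = Path(path)
    img = np.asarray(struct, dtype=float)[bscan]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.imshow(np.log1p(img), cmap="gray", aspect="auto",
              interpolation="nearest")
    x = np.arange(img.shape[1])
    for name in BOUNDARY_NAMES:
        ax.plot(x, seg.boundaries[name].depth[bscan], lw=1.0,
                color=_COLORS[name], label=name)
    ax.set_xlabel("A-line")
    ax.set_ylabel("depth (px)")
    ax.legend(fontsize=6, loc="lower right", ncols=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
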