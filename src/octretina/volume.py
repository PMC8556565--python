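"""The central raster container for OCT BM-scan data.

An acquisition consists of ``n_bscans`` lateral positions; at each position
``n_repeats`` consecutive B-scans are recorded (a BM-scan), each a 2-D image
of ``n_depth`` axial pixels by ``n_alines`` lateral A-lines.  Depth index 0
is the most anterior pixel (vitreous side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class OCTVolume:
    """4-D OCT intensity volume indexed ``(bscan, repeat, depth, aline)``.

    Parameters
    ----------
    data
        Nonnegative intensity array, shape ``(n_bscans, n_repeats, n_depth,
        n_alines)``.
    axial_scale_um
        Micrometres per depth pixel *in tissue*.
    lateral_scale_um
        Micrometres per A-line step (assumed equal along both lateral axes).
    meta
        Free-form metadata (seed, config hash, provenance ...).
    """

    data: np.ndarray
    axial_scale_um: float
    lateral_scale_um: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"OCTVolume data must be 4-D (bscan, repeat, depth, aline); "
                f"got shape {self.data.shape}"
            )
        if self.axial_scale_um <= 0 or self.lateral_scale_um <= 0:
            raise ValueError("pixel scales must be positive")

    @property
    def n_bscans(self) -> int:
        return self.data.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.data.shape[1]

    @property
    def n_depth(self) -> int:
        return self.data.shape[2]

    @property
    def n_alines(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "OCTVolume":
        """Return a copy of this volume carrying ``data`` and the same scales."""
        return OCTVolume(
            data=data,
            axial_scale_um=self.axial_scale_um,
            lateral_scale_um=self.lateral_scale_um,
            meta=dict(self.meta),
        )
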