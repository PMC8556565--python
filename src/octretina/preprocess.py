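"""Volume reconstruction and cleanup.

Order of operations for a raw acquisition: numerical dispersion
compensation (when spectral fringes are available), background
subtraction, SNR roll-off correction, rigid inter-B-scan registration,
and intensity averaging of the repeated frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .volume import OCTVolume

__all__ = [
    "DispersionCoefficients",
    "RegistrationResult",
    "compensate_dispersion",
    "subtract_background",
    "correct_rolloff",
    "register_bscans",
    "average_frames",
    "fwhm",
]


@dataclass(frozen=True)
class DispersionCoefficients:
    """Second/third-order dispersion phase coefficients.

    ``a2`` in rad per (sample index)^2, ``a3`` in rad per (sample index)^3,
    both relative to the centre sample ``k0_index`` (``None``: spectrum
    midpoint).
    """

    a2: float = 0.0
    a3: float = 0.0
    k0_index: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a2) and np.isfinite(self.a3)):
            raise ValueError("dispersion coefficients must be finite")


def compensate_dispersion(
    fringes: np.ndarray,
    coeffs: DispersionCoefficients,
    oversample: int = 1,
) -> np.ndarray:
    """Phase-correct a spectral fringe and transform it to an A-line.

    Multiplies the k-domain spectrum by
    ``exp(-1j*(a2*(k-k0)**2 + a3*(k-k0)**3))`` — cancelling a dispersive
    phase of the same coefficients — then Fourier-transforms to depth and
    returns the magnitude.  ``oversample`` zero-pads the spectrum by that
    factor for sub-pixel peak measurements; the returned axis is in units of
    ``1/oversample`` depth pixels.

    Works on a single spectrum or on a stack with spectra along the last
    axis.
    """
    f = np.asarray(fringes)
    if f.shape[-1] < 2:
        raise ValueError("fringes must hold at least 2 spectral samples")
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    n = f.shape[-1]
    k = np.arange(n, dtype=float)
    k0 = (n - 1) / 2.0 if coeffs.k0_index is None else float(coeffs.k0_index)
    dk = k - k0
    corrected = f * np.exp(-1j * (coeffs.a2 * dk**2 + coeffs.a3 * dk**3))
    if oversample > 1:
        pad = [(0, 0)] * (corrected.ndim - 1) + [(0, n * (oversample - 1))]
        corrected = np.pad(corrected, pad)
    return np.abs(np.fft.fft(corrected, axis=-1))


def fwhm(profile: np.ndarray, dx: float = 1.0) -> float:
    """Full width at half maximum of a single-peaked profile.

    Peak position from the global maximum; half-maximum crossings located by
    linear interpolation on either side.
    """
    p = np.asarray(profile, dtype=float)
    i = int(np.argmax(p))
    half = p[i] / 2.0
    if p[i] <= 0:
        raise ValueError("profile has no positive peak")
    lo = i
    while lo > 0 and p[lo] > half:
        lo -= 1
    if p[lo] > half:
        left = float(lo)
    else:
        left = lo + (half - p[lo]) / (p[lo + 1] - p[lo])
    hi = i
    n = p.size
    while hi < n - 1 and p[hi] > half:
        hi += 1
    if p[hi] > half:
        right = float(hi)
    else:
        right = hi - (half - p[hi]) / (p[hi - 1] - p[hi])
    return (right - left) * dx


def subtract_background(vol: OCTVolume, bg: OCTVolume) -> OCTVolume:
    """Subtract the mean depth profile of a background volume, clip at 0.

    The background is acquired outside the field of view, so only its
    depth-resolved statistics generalise: the profile is the background
    intensity averaged over B-scans, repeats and A-lines.
    """
    if bg.data.shape[2] != vol.data.shape[2]:
        raise ValueError(
            f"background depth axis {bg.data.shape[2]} does not match "
            f"volume depth axis {vol.data.shape[2]}"
        )
    profile = bg.data.mean(axis=(0, 1, 3))  # (depth,)
    out = vol.data - profile[None, None, :, None]
    np.clip(out, 0.0, None, out=out)
    return vol.with_data(out)


def correct_rolloff(vol: OCTVolume, decay: float) -> OCTVolume:
    """Undo an exponential depth roll-off: depth z is scaled by decay**-z."""
    if decay <= 0:
        raise ValueError("decay must be positive")
    z = np.arange(vol.n_depth, dtype=float)
    gain = decay ** (-z)
    return vol.with_data(vol.data * gain[None, None, :, None])


@dataclass
class RegistrationResult:
    """Cumulative per-B-scan rigid shifts and the re-aligned volume."""

    shifts: list[tuple[float, float]]  # (dz, dx) applied to each B-scan
    registered: OCTVolume


def _shift_image(img: np.ndarray, dz: float, dx: float, subpixel: bool) -> np.ndarray:
    if not subpixel:
        return np.roll(np.roll(img, int(round(dz)), axis=0), int(round(dx)), axis=1)
    return ndimage.shift(img, (dz, dx), order=1, mode="grid-wrap")


def register_bscans(
    vol: OCTVolume, upsample_factor: int = 1, match_smooth: int = 5
) -> RegistrationResult:
    """Align each B-scan to the previously aligned one by rigid translation.

    The first B-scan is the reference and keeps shift (0, 0).  Matching uses
    the repeat-averaged image, box-smoothed by ``match_smooth`` pixels so
    the (uncorrelated) speckle of neighbouring B-scans does not drive the
    correlation peak, and FFT cross-correlation; shifts are integer-pixel
    unless ``upsample_factor > 1``.  Constant (feature-free) images yield a
    zero shift.
    """
    if vol.n_bscans < 1:
        raise ValueError("volume must contain at least one B-scan")
    subpixel = upsample_factor > 1
    data = vol.data.copy()
    shifts: list[tuple[float, float]] = [(0.0, 0.0)]

    def _match_image(frames: np.ndarray) -> np.ndarray:
        img = frames.mean(axis=0)
        if match_smooth > 1:
            img = ndimage.uniform_filter(img, match_smooth, mode="reflect")
        return img

    ref = _match_image(data[0])
    for b in range(1, vol.n_bscans):
        moving = _match_image(data[b])
        if moving.std() == 0 or ref.std() == 0:
            dz = dx = 0.0
        else:
            (dz, dx), _, _ = phase_cross_correlation(
                ref, moving, upsample_factor=upsample_factor, normalization=None
            )
        if dz != 0 or dx != 0:
            for t in range(vol.n_repeats):
                data[b, t] = _shift_image(data[b, t], dz, dx, subpixel)
        shifts.append((float(dz), float(dx)))
        ref = _match_image(data[b])
    out = vol.with_data(data)
    return RegistrationResult(shifts=shifts, registered=out)


def average_frames(vol: OCTVolume) -> np.ndarray:
    """Structural volume: mean intensity over the repeat axis.

    Returns a 3-D array ``(bscan, depth, aline)``.  Averaging N frames with
    independent noise reduces the temporal fluctuation by about 1/sqrt(N).
    """
    return vol.data.mean(axis=1)
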