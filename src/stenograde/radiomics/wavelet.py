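"""Single-level undecimated 2D wavelet decomposition of the ROI.

Separable FIR filtering with the Coiflet-1 analysis taps, symmetric boundary
handling, no downsampling: each band keeps the ROI's spatial shape. Band names
are two letters, the first for the filter applied along rows (vertical axis),
the second along columns — ``LH`` is low-pass vertical, high-pass horizontal.

The undecimated (a trous) convention is used because the ROI width (41) is odd
and because shape-preserving bands keep the per-image-type feature extraction
uniform; the transform's fourfold redundancy means band energies of an interior
impulse sum to 4x the impulse energy for an orthonormal kernel.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import correlate1d

__all__ = ["wavelet_decompose", "BAND_NAMES"]

BAND_NAMES = ("LL", "LH", "HL", "HH")


def wavelet_decompose(
    pixels: np.ndarray, wavelet: str = "coif1"
) -> dict[str, np.ndarray]:
    """Decompose a 2D image into shape-preserving LL/LH/HL/HH bands."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2:
        raise ValueError("expected a 2D image")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite values")
    wav = pywt.Wavelet(wavelet)
    lo = np.asarray(wav.dec_lo, dtype=float)
    hi = np.asarray(wav.dec_hi, dtype=float)
    rows = {
        "L": correlate1d(pixels, lo, axis=0, mode="reflect"),
        "H": correlate1d(pixels, hi, axis=0, mode="reflect"),
    }
    return {
        r + c: correlate1d(rows[r], f, axis=1, mode="reflect")
        for r in ("L", "H")
        for c, f in (("L", lo), ("H", hi))
    }
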