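"""Single-level 3-D wavelet filter bank.

An undecimated (stationary) separable decomposition with the Coiflet-1
filters: the low- and high-pass analysis filters are applied along each axis
in turn with symmetric boundary handling, giving the 8 sub-bands LLL..HHH,
each on the input grid so the original ROI mask applies unchanged.  The
letter at position *i* of a band name is the filter applied along array
axis *i* (axis 0 = slice direction).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import correlate1d

from ..imaging import VoxelImage
from .names import WAVELET_BANDS

WAVELET_NAME = "coif1"


def _filters() -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(WAVELET_NAME)
    return np.asarray(w.dec_lo), np.asarray(w.dec_hi)


def wavelet_decompose(image: VoxelImage) -> dict[str, VoxelImage]:
    """Return the 8 labelled sub-band images of a volume."""
    if any(n < 2 for n in image.values.shape):
        raise ValueError("wavelet decomposition needs at least 2 voxels per axis")
    lo, hi = _filters()
    bands: dict[str, VoxelImage] = {}
    # filter each axis once, reusing partial results: axis-0 pass, then 1, then 2
    partial0 = {
        "L": correlate1d(image.values, lo, axis=0, mode="reflect"),
        "H": correlate1d(image.values, hi, axis=0, mode="reflect"),
    }
    partial1 = {
        k0 + k1: correlate1d(arr, f, axis=1, mode="reflect")
        for k0, arr in partial0.items()
        for k1, f in (("L", lo), ("H", hi))
    }
    for name in WAVELET_BANDS:
        f = lo if name[2] == "L" else hi
        bands[name] = image.copy_with(correlate1d(partial1[name[:2]], f, axis=2, mode="reflect"))
    return bands
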