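"""First-order (intensity histogram) features.

All moments are population moments (no small-sample correction); Kurtosis is
uncorrected (a Gaussian scores ~3).  Entropy and Uniformity are computed on
the fixed-bin-width discretised levels, everything else on raw intensities.
Degenerate statistics on a constant ROI (Skewness, Kurtosis) return 0.
"""

from __future__ import annotations

import numpy as np

from ..imaging import DiscretizedROI


def compute_first_order(
    intensities: np.ndarray,
    discretized: DiscretizedROI,
    voxel_volume: float,
) -> dict[str, float]:
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("cannot compute first-order features on an empty ROI")
    n = x.size
    mean = float(x.mean())
    dev = x - mean
    m2 = float(np.mean(dev**2))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    robust = x[(x >= p10) & (x <= p90)]
    if robust.size:
        rmad = float(np.mean(np.abs(robust - robust.mean())))
    else:
        rmad = 0.0

    counts = np.bincount(discretized.levels, minlength=discretized.n_levels + 1)[1:]
    p = counts[counts > 0] / n

    energy = float(np.sum(x**2))
    feats = {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": float(np.mean(dev**4) / m2**2) if m2 > 0 else 0.0,
        "Maximum": float(x.max()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "Mean": mean,
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(np.mean(dev**3) / m2**1.5) if m2 > 0 else 0.0,
        "TotalEnergy": float(voxel_volume) * energy,
        "Uniformity": float(np.sum(p**2)),
        "Variance": m2,
    }
    return feats
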