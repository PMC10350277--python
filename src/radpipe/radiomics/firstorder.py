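"""First-order (intensity histogram) features of an ROI, 18 in total."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["FIRSTORDER_FEATURES", "first_order_features"]

FIRSTORDER_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def first_order_features(data: np.ndarray, mask: np.ndarray,
                         voxel_volume: float = 1.0,
                         n_bins: int = 32) -> dict[str, float]:
    """The 18 first-order statistics of the ROI intensities.

    Entropy and Uniformity are computed on the fixed-bin-count histogram
    (``n_bins`` equal-width bins over the ROI range); Variance, Skewness
    and Kurtosis are population moments, with Kurtosis not excess-corrected
    (a normal sample gives ~3).  TotalEnergy scales Energy by the physical
    voxel volume in mm^3.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    x = np.asarray(data, dtype=float)[mask]
    n = x.size
    mean = float(x.mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    else:
        hist = np.array([n])
    p = hist[hist > 0] / n

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if x.max() == x.min():  # constant ROI: all moments degenerate
        var, skew, kurt = 0.0, 0.0, 0.0
    else:
        var = float(x.var())  # population
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x, fisher=False))

    energy = float((x ** 2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * float(voxel_volume),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p ** 2).sum()),
    }
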