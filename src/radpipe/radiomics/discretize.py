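"""Fixed-bin-count gray-level discretization of ROI intensities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedRoi", "discretize_fixed_bin_count"]


@dataclass
class DiscretizedRoi:
    """ROI voxels mapped to gray-level bins 1..n_bins.

    ``bins`` is an integer array on the full grid: 0 outside the ROI,
    1..n_bins inside.  ``bin_edges`` are the n_bins+1 uniform edges over
    the ROI intensity range (equal to [min, min] for a constant ROI).
    """

    bins: np.ndarray
    mask: np.ndarray
    n_bins: int
    bin_edges: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def roi_bins(self) -> np.ndarray:
        """Bin indices of the ROI voxels only (1..n_bins)."""
        return self.bins[self.mask]


def discretize_fixed_bin_count(data: np.ndarray, mask: np.ndarray,
                               n_bins: int = 32) -> DiscretizedRoi:
    """Map ROI intensities to ``n_bins`` equal-width bins over [min, max].

    Bins are half-open [edge_k, edge_{k+1}) except the last, which is
    closed so the maximum falls in bin ``n_bins``.  A constant ROI is
    assigned entirely to bin 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot discretize an empty ROI")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    data = np.asarray(data, dtype=float)
    vals = data[mask]
    lo, hi = float(vals.min()), float(vals.max())

    bins = np.zeros(data.shape, dtype=np.int64)
    if hi == lo:
        bins[mask] = 1
        edges = np.full(n_bins + 1, lo)
        return DiscretizedRoi(bins, mask, n_bins, edges)

    width = (hi - lo) / n_bins
    b = np.floor((vals - lo) / width).astype(np.int64) + 1
    np.clip(b, 1, n_bins, out=b)
    bins[mask] = b
    edges = lo + width * np.arange(n_bins + 1)
    return DiscretizedRoi(bins, mask, n_bins, edges)
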