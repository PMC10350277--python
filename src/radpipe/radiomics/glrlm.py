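"""Gray-level run-length matrix (GLRLM) texture features.

A run is a maximal set of collinear ROI voxels sharing a gray level.
Runs are enumerated per direction over the 13 unique 3D directions and
the 16 features are averaged over directions (averaged aggregation).
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedRoi
from .glcm import ALL_DIRECTIONS_3D

__all__ = ["GLRLM_FEATURES", "glrlm_matrix", "glrlm_features"]

GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def _shifted(arr: np.ndarray, offset: tuple[int, int, int],
             fill: int = 0) -> np.ndarray:
    """Array whose value at voxel v is arr[v + offset] (``fill`` off-grid)."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for n, o in zip(arr.shape, offset):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def glrlm_matrix(droi: DiscretizedRoi,
                 direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length count matrix R(g, r) for one direction.

    Shape (Ng, Rmax) with Rmax the longest run observed; every ROI voxel
    belongs to exactly one run, so sum_g sum_r r * R(g, r) = Np.
    """
    bins = droi.bins
    d = tuple(int(x) for x in direction)
    neg = tuple(-x for x in d)

    prev = _shifted(bins, neg)  # bin of voxel v - d
    in_roi = bins > 0
    starts = in_roi & (prev != bins)

    nxt = _shifted(bins, d)  # bin of voxel v + d
    same_next = in_roi & (nxt == bins) & (nxt > 0)

    # run length at each start = 1 + number of consecutive same-bin successors
    lengths = np.ones(bins.shape, dtype=np.int64)
    alive = same_next.copy()
    step = 1
    while alive.any():
        lengths += alive
        alive = alive & _shifted(same_next, tuple(x * step for x in d), 0).astype(bool)
        step += 1

    g = bins[starts]
    r = lengths[starts]
    if g.size == 0:
        return np.zeros((droi.n_bins, 1), dtype=float)
    rmax = int(r.max())
    mat = np.zeros((droi.n_bins, rmax), dtype=float)
    np.add.at(mat, (g - 1, r - 1), 1.0)
    return mat


def _features_from_matrix(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, rmax = mat.shape
    g = np.arange(1, ng + 1, dtype=float)[:, None]
    r = np.arange(1, rmax + 1, dtype=float)[None, :]
    nr = mat.sum()
    pg = mat.sum(axis=1)  # per-gray-level run counts
    pr = mat.sum(axis=0)  # per-length run counts
    p = mat / nr

    mu_g = float((g * p).sum())
    mu_r = float((r * p).sum())
    p_nz = p[p > 0]

    return {
        "ShortRunEmphasis": float((mat / r ** 2).sum() / nr),
        "LongRunEmphasis": float((mat * r ** 2).sum() / nr),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum() / nr ** 2),
        "RunLengthNonUniformity": float((pr ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pr ** 2).sum() / nr ** 2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((((g - mu_g) ** 2) * p).sum()),
        "RunVariance": float((((r - mu_r) ** 2) * p).sum()),
        "RunEntropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "LowGrayLevelRunEmphasis": float((mat / g ** 2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((mat * g ** 2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((mat / (g ** 2 * r ** 2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((mat * g ** 2 / r ** 2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((mat * r ** 2 / g ** 2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((mat * r ** 2 * g ** 2).sum() / nr),
    }


def glrlm_features(droi: DiscretizedRoi,
                   directions: tuple[tuple[int, int, int], ...] = ALL_DIRECTIONS_3D
                   ) -> dict[str, float]:
    """16 GLRLM features averaged over run directions."""
    if droi.n_voxels < 1:
        raise ValueError("GLRLM requires a nonempty ROI")
    n_vox = droi.n_voxels
    per_dir = []
    for d in directions:
        mat = glrlm_matrix(droi, d)
        if mat.sum() > 0:
            per_dir.append(_features_from_matrix(mat, n_vox))
    return {name: float(np.mean([f[name] for f in per_dir]))
            for name in GLRLM_FEATURES}
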