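"""Gray-level co-occurrence matrix (GLCM) texture features.

Co-occurrences are accumulated per displacement vector over the 13 unique
3D directions at distance 1, symmetrized and normalized; the 24 features
are computed per direction and averaged (averaged aggregation).
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedRoi

__all__ = ["ALL_DIRECTIONS_3D", "GLCM_FEATURES", "glcm_matrix", "glcm_features"]

_EPS = np.spacing(1.0)


def _unique_directions() -> list[tuple[int, int, int]]:
    dirs = []
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                d = (a, b, c)
                if d == (0, 0, 0):
                    continue
                # keep one representative of each +/- pair
                if d > (0, 0, 0):
                    dirs.append(d)
    return dirs


#: The 13 unique 3D neighbour directions (opposite pairs merged).
ALL_DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(_unique_directions())

GLCM_FEATURES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)


def _pair_slices(shape, offset):
    """Slices (src, dst) so that src voxel v pairs with dst voxel v+offset."""
    src, dst = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def glcm_matrix(droi: DiscretizedRoi, direction: tuple[int, int, int],
                distance: int = 1) -> np.ndarray:
    """Symmetrized, normalized co-occurrence probability matrix for one
    displacement vector.  Returns an Ng x Ng array summing to 1 (all-zero
    if the direction yields no valid voxel pair)."""
    ng = droi.n_bins
    off = tuple(int(d) * distance for d in direction)
    src, dst = _pair_slices(droi.bins.shape, off)
    a = droi.bins[src]
    b = droi.bins[dst]
    valid = (a > 0) & (b > 0)
    counts = np.zeros((ng, ng), dtype=float)
    if valid.any():
        i = a[valid] - 1
        j = b[valid] - 1
        np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T  # symmetrize
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def _features_from_matrix(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt((((i - mu_x) ** 2) * px).sum()))
    sig_y = float(np.sqrt((((i - mu_y) ** 2) * py).sum()))

    # difference |i-j| and sum i+j marginals
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())

    nz = p > 0
    joint_entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    pxpy = np.outer(px, py)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz] + _EPS)).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    da = float((k_diff * p_diff).sum())
    contrast = float((((ii - jj) ** 2) * p).sum())
    corr = 1.0
    if sig_x > 0 and sig_y > 0:
        corr = float(((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))

    imc1 = 0.0
    if max(hx, hy) > 0:
        imc1 = (joint_entropy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    # MCC: second largest eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    mcc = 1.0
    occupied = px > 0
    if occupied.sum() > 1:
        psub = p[np.ix_(occupied, occupied)]
        pxs = px[occupied]
        pys = py[occupied]
        q = (psub / pxs[:, None]) @ (psub / pys[:, None]).T
        ev = np.linalg.eigvals(q)
        ev = np.sort(np.abs(ev))[::-1]
        mcc = float(np.sqrt(max(0.0, ev[1].real if np.iscomplexobj(ev) else ev[1])))

    absdiff = np.abs(ii - jj)
    offdiag = absdiff > 0
    inv_var = float((p[offdiag] / (absdiff[offdiag] ** 2)).sum())

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu_x,
        "ClusterProminence": float((((ii + jj - mu_x - mu_y) ** 4) * p).sum()),
        "ClusterShade": float((((ii + jj - mu_x - mu_y) ** 3) * p).sum()),
        "ClusterTendency": float((((ii + jj - mu_x - mu_y) ** 2) * p).sum()),
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff[p_diff > 0]
                                     * np.log2(p_diff[p_diff > 0])).sum()),
        "DifferenceVariance": float((((k_diff - da) ** 2) * p_diff).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": joint_entropy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) ** 2) / ng ** 2)).sum()),
        "Id": float((p / (1.0 + absdiff)).sum()),
        "Idn": float((p / (1.0 + absdiff / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "SumSquares": float((((ii - mu_x) ** 2) * p).sum()),
        "MCC": mcc,
    }


def glcm_features(droi: DiscretizedRoi, distance: int = 1,
                  directions: tuple[tuple[int, int, int], ...] = ALL_DIRECTIONS_3D
                  ) -> dict[str, float]:
    """24 GLCM features, computed per direction and averaged over the
    directions that yield at least one voxel pair."""
    if droi.n_voxels < 2:
        raise ValueError("GLCM requires at least 2 ROI voxels")
    per_dir = []
    for d in directions:
        p = glcm_matrix(droi, d, distance)
        if p.sum() > 0:
            per_dir.append(_features_from_matrix(p))
    if not per_dir:
        raise ValueError("no valid voxel pairs in any direction")
    return {name: float(np.mean([f[name] for f in per_dir]))
            for name in GLCM_FEATURES}
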