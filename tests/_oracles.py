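"""Independent brute-force oracles used by the tests.

Everything here is written as plainly as possible — nested Python loops,
no shared code with the package internals — so that agreement with the
vectorized implementations is meaningful.
"""

from __future__ import annotations

import numpy as np


def brute_glcm_matrix(bins: np.ndarray, direction, ng: int) -> np.ndarray:
    """Symmetrized normalized co-occurrence matrix by explicit voxel-pair
    enumeration (bins: 0 outside ROI, 1..ng inside)."""
    counts = np.zeros((ng, ng))
    shape = bins.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if bins[i, j, k] == 0:
                    continue
                ii, jj, kk = i + direction[0], j + direction[1], k + direction[2]
                if not (0 <= ii < shape[0] and 0 <= jj < shape[1]
                        and 0 <= kk < shape[2]):
                    continue
                if bins[ii, jj, kk] == 0:
                    continue
                counts[bins[i, j, k] - 1, bins[ii, jj, kk] - 1] += 1
    counts = counts + counts.T
    if counts.sum() > 0:
        counts = counts / counts.sum()
    return counts


def brute_glrlm_matrix(bins: np.ndarray, direction, ng: int) -> np.ndarray:
    """Run-length matrix by explicit run walking."""
    shape = bins.shape
    runs = []  # (gray, length)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                g = bins[i, j, k]
                if g == 0:
                    continue
                pi = (i - direction[0], j - direction[1], k - direction[2])
                if (0 <= pi[0] < shape[0] and 0 <= pi[1] < shape[1]
                        and 0 <= pi[2] < shape[2] and bins[pi] == g):
                    continue  # not a run start
                length = 1
                ci, cj, ck = i + direction[0], j + direction[1], k + direction[2]
                while (0 <= ci < shape[0] and 0 <= cj < shape[1]
                       and 0 <= ck < shape[2] and bins[ci, cj, ck] == g):
                    length += 1
                    ci += direction[0]
                    cj += direction[1]
                    ck += direction[2]
                runs.append((g, length))
    if not runs:
        return np.zeros((ng, 1))
    rmax = max(r for _, r in runs)
    mat = np.zeros((ng, rmax))
    for g, r in runs:
        mat[g - 1, r - 1] += 1
    return mat


def naive_glcm_subset(p: np.ndarray) -> dict[str, float]:
    """A few GLCM features by direct double loops over the matrix."""
    ng = p.shape[0]
    contrast = 0.0
    entropy = 0.0
    mu_x = mu_y = 0.0
    for i in range(ng):
        for j in range(ng):
            mu_x += (i + 1) * p[i, j]
            mu_y += (j + 1) * p[i, j]
    sx = sy = cov = 0.0
    for i in range(ng):
        for j in range(ng):
            contrast += (i - j) ** 2 * p[i, j]
            if p[i, j] > 0:
                entropy -= p[i, j] * np.log2(p[i, j])
            sx += (i + 1 - mu_x) ** 2 * p[i, j]
            sy += (j + 1 - mu_y) ** 2 * p[i, j]
            cov += (i + 1 - mu_x) * (j + 1 - mu_y) * p[i, j]
    corr = cov / np.sqrt(sx * sy) if sx > 0 and sy > 0 else 1.0
    return {"Contrast": contrast, "JointEntropy": entropy, "Correlation": corr,
            "SumSquares": sx, "MaximumProbability": float(p.max())}


def naive_glrlm_subset(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The four signature run-length features by direct loops."""
    ng, rmax = mat.shape
    nr = mat.sum()
    sre = lre = 0.0
    for g in range(ng):
        for r in range(rmax):
            sre += mat[g, r] / (r + 1) ** 2
            lre += mat[g, r] * (r + 1) ** 2
    p_r = mat.sum(axis=0) / nr
    mu_r = sum((r + 1) * p_r[r] for r in range(rmax))
    rv = sum(p_r[r] * (r + 1 - mu_r) ** 2 for r in range(rmax))
    return {"ShortRunEmphasis": sre / nr, "LongRunEmphasis": lre / nr,
            "RunPercentage": nr / n_voxels, "RunVariance": rv}


def brute_cindex(scores, time, event) -> float:
    """Harrell's C by exhaustive ordered-pair enumeration."""
    num = 0.0
    den = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def gaussian_3x3x3_stencil(sigma: float) -> np.ndarray:
    """Truncated normalized 3D Gaussian kernel by explicit enumeration."""
    k = np.zeros((3, 3, 3))
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                k[a + 1, b + 1, c + 1] = np.exp(
                    -(a * a + b * b + c * c) / (2 * sigma * sigma))
    return k / k.sum()
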