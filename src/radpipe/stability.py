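"""ROI-perturbation stability screening of radiomic features.

Small in-plane translations of the tumor mask (+/- 10% of the bounding-box
length along x and y) mimic inter-reader segmentation variability; features
whose intra-class correlation coefficient ICC(2,1) across the perturbed
extractions exceeds 0.75 are considered stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import RoiMask

__all__ = ["PerturbationSet", "IccReport", "perturb_mask", "icc",
           "stability_screen"]


@dataclass
class PerturbationSet:
    """The original mask plus its four single-axis in-plane translations
    (+x, -x, +y, -y); 5 measurement conditions in total."""

    original: RoiMask
    shifted: list[RoiMask]
    shifts: list[tuple[int, int, int]]
    fraction: float

    @property
    def conditions(self) -> list[RoiMask]:
        return [self.original] + self.shifted

    @property
    def n_conditions(self) -> int:
        return 1 + len(self.shifted)


def _shift_mask(data: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Translate the mask by whole voxels; voxels pushed off-grid are
    clipped away (with a warning at the call site if any are lost)."""
    out = np.zeros_like(data)
    src, dst = [], []
    for n, o in zip(data.shape, offset):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = data[tuple(src)]
    return out


def perturb_mask(mask: RoiMask, fraction: float = 0.10) -> PerturbationSet:
    """Build the 5-condition perturbation set of a mask.

    Shift magnitude per in-plane axis = round(fraction x bounding-box
    length), with a minimum of one voxel (warned when the minimum rule
    engages).  The slice axis (z) is never shifted.
    """
    if mask.n_voxels == 0:
        raise ValueError("cannot perturb an empty mask")
    bbox = mask.bounding_box_lengths()
    shifted, shifts = [], []
    for axis in (0, 1):  # in-plane axes only
        mag = int(round(fraction * bbox[axis]))
        if mag < 1:
            warnings.warn(
                f"axis {axis}: {fraction:.0%} of bbox length {bbox[axis]} "
                "rounds below 1 voxel; using the 1-voxel minimum shift")
            mag = 1
        for sign in (+1, -1):
            off = [0, 0, 0]
            off[axis] = sign * mag
            data = _shift_mask(mask.data, tuple(off))
            lost = mask.n_voxels - int(data.sum())
            if data.sum() == 0:
                raise ValueError(f"shift {tuple(off)} pushes mask fully off-grid")
            if lost > 0:
                warnings.warn(f"shift {tuple(off)} clipped {lost} voxel(s) "
                              "at the grid boundary")
            shifted.append(RoiMask(data, mask.spacing))
            shifts.append(tuple(off))
    return PerturbationSet(mask, shifted, shifts, fraction)


def icc(measurements: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measurement, on a subjects x conditions matrix.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    Defined as 0 (with a warning) when there is no between-subject
    variance at all.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix, >=2 each")
    if not np.all(np.isfinite(x)):
        raise ValueError("measurements must be finite")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()

    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        warnings.warn("zero between-subject variance; ICC defined as 0")
        return 0.0
    return float((msr - mse) / denom)


@dataclass
class IccReport:
    """Per-feature ICC values with the stability decision (ICC strictly
    above the threshold)."""

    table: pd.DataFrame  # columns: feature, icc, stable
    threshold: float = 0.75

    @property
    def stable_features(self) -> list[str]:
        return self.table.loc[self.table["stable"], "feature"].tolist()


def stability_screen(features_per_condition: list[pd.DataFrame],
                     threshold: float = 0.75) -> IccReport:
    """Screen features for robustness across perturbation conditions.

    ``features_per_condition`` holds one patients x features table per
    measurement condition (identical columns and row order).  Features
    with ICC > threshold are retained, in their original column order.
    """
    if len(features_per_condition) < 2:
        raise ValueError("need at least 2 conditions")
    cols = list(features_per_condition[0].columns)
    for df in features_per_condition[1:]:
        if list(df.columns) != cols:
            raise ValueError("feature sets differ between conditions")
        if len(df) != len(features_per_condition[0]):
            raise ValueError("patient counts differ between conditions")

    rows = []
    for name in cols:
        m = np.column_stack([df[name].to_numpy(dtype=float)
                             for df in features_per_condition])
        if not np.all(np.isfinite(m)):
            rows.append((name, np.nan, False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = icc(m)
        rows.append((name, val, bool(val > threshold)))
    table = pd.DataFrame(rows, columns=["feature", "icc", "stable"])
    return IccReport(table, threshold)
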