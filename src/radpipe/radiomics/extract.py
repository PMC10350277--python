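"""Per-patient assembly of the full 1072-feature radiomic vector.

Per modality (T1w, T2w): 14 shape + 18 first-order + 40 texture
(24 GLCM + 16 GLRLM) on the original image, and 58 first-order+texture
features on each of the 8 stationary-wavelet sub-bands (464), i.e. 536
features per modality and 1072 in total.  Feature names follow
``T_{T1|T2}_{original|waveletXXX}_{class}_{FeatureName}``, e.g.
``T_T2_waveletLLL_glrlm_LongRunEmphasis``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..volume import ImageVolume, RoiMask
from .discretize import discretize_fixed_bin_count
from .firstorder import FIRSTORDER_FEATURES, first_order_features
from .glcm import ALL_DIRECTIONS_3D, GLCM_FEATURES, glcm_features
from .glrlm import GLRLM_FEATURES, glrlm_features
from .shape import SHAPE_FEATURES, shape_features
from .wavelet import SUBBAND_LABELS, wavelet_subbands

__all__ = ["ExtractionConfig", "extract_modality", "extract_all",
           "feature_name_inventory", "N_FEATURES_TOTAL", "N_FEATURES_PER_MODALITY"]

N_FEATURES_PER_MODALITY = 536
N_FEATURES_TOTAL = 1072


@dataclass
class ExtractionConfig:
    """Extraction parameters: gray-level bin count, wavelet kernel, GLCM
    displacement distance, and the texture direction set."""

    n_bins: int = 32
    wavelet: str = "coif1"
    glcm_distance: int = 1
    directions: tuple[tuple[int, int, int], ...] = field(
        default=ALL_DIRECTIONS_3D)

    def to_dict(self) -> dict:
        return {"n_bins": self.n_bins, "wavelet": self.wavelet,
                "glcm_distance": self.glcm_distance,
                "directions": [list(d) for d in self.directions]}


def _modality_tag(modality: str) -> str:
    m = modality.rstrip("w")
    if m not in ("T1", "T2"):
        raise ValueError(f"modality must be T1w or T2w, got {modality!r}")
    return m


def _texture_block(data: np.ndarray, mask: np.ndarray, voxel_volume: float,
                   cfg: ExtractionConfig) -> dict[str, dict[str, float]]:
    """First-order + GLCM + GLRLM on one (sub-band) image, with the
    gray-level discretization recomputed for that image."""
    droi = discretize_fixed_bin_count(data, mask, cfg.n_bins)
    return {
        "firstorder": first_order_features(data, mask, voxel_volume, cfg.n_bins),
        "glcm": glcm_features(droi, cfg.glcm_distance, cfg.directions),
        "glrlm": glrlm_features(droi, cfg.directions),
    }


def extract_modality(vol: ImageVolume, mask: RoiMask,
                     cfg: ExtractionConfig | None = None) -> dict[str, float]:
    """The 536 features of one modality, in canonical order."""
    cfg = cfg or ExtractionConfig()
    tag = _modality_tag(vol.modality)
    if vol.shape != mask.shape:
        raise ValueError("volume and mask must share the same grid")
    out: dict[str, float] = {}

    for name, value in shape_features(mask).items():
        out[f"T_{tag}_original_shape_{name}"] = value

    blocks = _texture_block(vol.data, mask.data, vol.voxel_volume, cfg)
    for cls, feats in blocks.items():
        for name, value in feats.items():
            out[f"T_{tag}_original_{cls}_{name}"] = value

    for label, band in wavelet_subbands(vol, cfg.wavelet).items():
        blocks = _texture_block(band.data, mask.data, vol.voxel_volume, cfg)
        for cls, feats in blocks.items():
            for name, value in feats.items():
                out[f"T_{tag}_wavelet{label}_{cls}_{name}"] = value

    assert len(out) == N_FEATURES_PER_MODALITY, len(out)
    return out


def extract_all(vol_t1: ImageVolume, vol_t2: ImageVolume, mask: RoiMask,
                cfg: ExtractionConfig | None = None) -> pd.Series:
    """The full 1072-feature vector of one patient (T1w block then T2w)."""
    cfg = cfg or ExtractionConfig()
    feats = extract_modality(vol_t1, mask, cfg)
    feats.update(extract_modality(vol_t2, mask, cfg))
    assert len(feats) == N_FEATURES_TOTAL, len(feats)
    return pd.Series(feats, dtype=float)


def feature_name_inventory(cfg: ExtractionConfig | None = None) -> list[str]:
    """The 1072 canonical feature names, without extracting anything."""
    names = []
    for tag in ("T1", "T2"):
        for f in SHAPE_FEATURES:
            names.append(f"T_{tag}_original_shape_{f}")
        for cls, fs in (("firstorder", FIRSTORDER_FEATURES),
                        ("glcm", GLCM_FEATURES), ("glrlm", GLRLM_FEATURES)):
            for f in fs:
                names.append(f"T_{tag}_original_{cls}_{f}")
        for label in SUBBAND_LABELS:
            for cls, fs in (("firstorder", FIRSTORDER_FEATURES),
                            ("glcm", GLCM_FEATURES), ("glrlm", GLRLM_FEATURES)):
                for f in fs:
                    names.append(f"T_{tag}_wavelet{label}_{cls}_{f}")
    return names
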