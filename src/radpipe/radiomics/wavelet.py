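"""Single-level undecimated 3D wavelet decomposition into 8 sub-bands.

The stationary (a trous) transform keeps every sub-band on the original
grid, so the tumor mask applies unchanged to each filtered image.  The
default kernel is coif1; sub-bands are labelled L/H per axis in axis
order, LLL ... HHH.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..volume import ImageVolume

__all__ = ["SUBBAND_LABELS", "wavelet_subbands"]

#: Label order: axis0, axis1, axis2; L = low-pass, H = high-pass.
SUBBAND_LABELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def wavelet_subbands(vol: ImageVolume, wavelet: str = "coif1"
                     ) -> dict[str, ImageVolume]:
    """Decompose a volume into its 8 single-level stationary sub-bands.

    Axes of odd length are symmetrically edge-padded to even length for
    the transform and cropped back, so every sub-band matches the input
    grid exactly.
    """
    w = pywt.Wavelet(wavelet)
    data = vol.data
    if min(data.shape) < w.dec_len:
        raise ValueError(
            f"volume shape {data.shape} smaller than {wavelet} filter "
            f"length {w.dec_len}")

    pad = [(0, n % 2) for n in data.shape]
    padded = np.pad(data, pad, mode="symmetric") if any(p[1] for p in pad) else data

    coeffs = pywt.swtn(padded, w, level=1)[0]
    crop = tuple(slice(0, n) for n in data.shape)

    out = {}
    for label in SUBBAND_LABELS:
        key = "".join("a" if c == "L" else "d" for c in label)
        out[label] = ImageVolume(coeffs[key][crop], vol.spacing, vol.modality)
    return out
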