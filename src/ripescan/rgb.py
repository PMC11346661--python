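"""Mean fruit-region color extraction and the RGB index catalog.

The catalog covers the normalized channel coordinates plus the standard
vegetation/color indices used for ripening assessment: IKAW, ExR, ExG, ExGR,
CIVE, GRRI, GRVI, NDI, VARI, VARI1, two normalized-difference variants and
the intensity index INT.

Naming notes
------------
* ``Rn`` is the red chromatic coordinate R/(R+G+B).  (Some tables typeset
  the formula with G in the numerator, which is the *green* coordinate; that
  quantity is exposed here as ``Gn``.  Red and orange fruit with rising Rn
  across ripening is only consistent with the R-numerator form.)
* Two distinct normalized-difference rows exist in the literature catalog:
  ``NDVI1 = (R-B)/(R+B)`` (identical to IKAW) and ``NDVI_rgb = (R-G)/(R+G)``
  (the negative of GRVI).  Both are kept under separate keys; the ``_rgb``
  suffix avoids a collision with the spectral NDVI.
* ``VARI1 = (G - VARI)/(G + VARI + B)`` is evaluated on raw 0-255 channels;
  on that scale it lands in the ~0.5-1.0 range observed for ripening fruit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RGBTriplet",
    "RGB_INDEX_NAMES",
    "extract_mean_rgb",
    "chromatic_coords",
    "compute_rgb_indices",
    "rgb_index_table",
]

RGB_INDEX_NAMES = (
    "Rn", "Bn", "Gn", "IKAW", "ExR", "ExG", "ExGR", "CIVE", "GRRI", "GRVI",
    "NDI", "VARI", "VARI1", "NDVI1", "NDVI_rgb", "INT",
)


@dataclass(frozen=True)
class RGBTriplet:
    """Mean red/green/blue channel intensities of a masked fruit region."""

    R: float
    G: float
    B: float

    def __post_init__(self) -> None:
        for name in ("R", "G", "B"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"channel {name} must be finite and >= 0, got {v}")


def extract_mean_rgb(image, mask_threshold: float = 30.0):
    """Mean channel intensities over the fruit region of a photograph.

    The fruit is assumed to sit on a dark background: the mask keeps pixels
    whose grayscale mean exceeds ``mask_threshold`` (default 30 on the 0-255
    scale).  Returns ``(RGBTriplet, n_pixels)``.

    Raises ``ValueError`` when no pixel passes the threshold.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {arr.shape}")
    rgb = arr[..., :3].astype(float)
    gray = rgb.mean(axis=2)
    mask = gray > mask_threshold
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no fruit pixels: mask is empty at this threshold")
    means = rgb[mask].mean(axis=0)
    return RGBTriplet(float(means[0]), float(means[1]), float(means[2])), n


def chromatic_coords(t: RGBTriplet) -> tuple[float, float, float]:
    """Chromatic coordinates (rn, gn, bn) = channel / (R+G+B)."""
    s = t.R + t.G + t.B
    if s <= 0:
        raise ValueError("R+G+B must be > 0 for chromatic coordinates")
    return t.R / s, t.G / s, t.B / s


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("index %s has a zero denominator; set to NaN", name)
        return math.nan
    return num / den


def compute_rgb_indices(t: RGBTriplet) -> dict[str, float]:
    """Evaluate the full RGB index catalog from mean channel intensities.

    Indices with a zero denominator for this particular triplet are reported
    as NaN (with a logged reason); all others are still computed.

    Exact internal identities (up to floating point): ``IKAW == NDVI1``,
    ``GRVI == -NDVI_rgb`` and ``ExGR == ExG - ExR``.
    """
    R, G, B = t.R, t.G, t.B
    rn, gn, bn = chromatic_coords(t)

    exr = 1.4 * rn - gn
    exg = 2.0 * gn - rn - bn
    vari = _safe_div(G - R, G + R - B, "VARI")

    out = {
        "Rn": rn,
        "Bn": bn,
        "Gn": gn,
        "IKAW": _safe_div(R - B, R + B, "IKAW"),
        "ExR": exr,
        "ExG": exg,
        "ExGR": exg - exr,
        "CIVE": 0.441 * R - 0.881 * G + 0.385 * B + 18.78745,
        "GRRI": _safe_div(G, R, "GRRI"),
        "GRVI": _safe_div(G - R, G + R, "GRVI"),
        "NDI": (rn - gn) / (rn + gn + 0.01),
        "VARI": vari,
        "VARI1": _safe_div(G - vari, G + vari + B, "VARI1") if math.isfinite(vari) else math.nan,
        "NDVI1": _safe_div(R - B, R + B, "NDVI1"),
        "NDVI_rgb": _safe_div(R - G, R + G, "NDVI_rgb"),
        "INT": (R + G + B) / 3.0,
    }
    return out


def rgb_index_table(rgb_df):
    """Catalog indices for a table of triplets (columns ``R``, ``G``, ``B``).

    Returns a DataFrame aligned to ``rgb_df.index`` with one column per
    catalog index.
    """
    import pandas as pd

    rows = [
        compute_rgb_indices(RGBTriplet(float(r.R), float(r.G), float(r.B)))
        for r in rgb_df.itertuples()
    ]
    return pd.DataFrame(rows, index=rgb_df.index)
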