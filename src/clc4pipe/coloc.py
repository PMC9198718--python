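"""Mander's colocalization coefficients on two-channel images.

The headline value is the intensity-weighted overlap coefficient

    R = sum(ch1*ch2) / sqrt(sum(ch1^2) * sum(ch2^2))

computed over the union of the two foreground masks on background-subtracted
intensities, together with the split coefficients M1 (fraction of channel-1
signal residing in channel-2 foreground) and M2 (symmetric). All three lie in
[0, 1] and are invariant under multiplying either channel by a positive
constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

from .images import ImagePair

__all__ = ["ColocResult", "threshold_channels", "manders_overlap"]


@dataclass(frozen=True)
class ColocResult:
    """Colocalization coefficients for one image pair."""

    overlap_coefficient: float  # Mander's R, the headline value
    m1: float
    m2: float
    thresholds: tuple[float, float]
    n_foreground_pixels: int
    defined: bool = True
    reason: str = ""


def threshold_channels(
    pair: ImagePair,
    method: str | tuple[float, float] = "otsu",
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Per-channel background thresholds and foreground masks.

    ``method`` is ``"otsu"`` (default) or a pair of fixed threshold values.
    Otsu on a constant image is undefined and raises with a hint to use fixed
    thresholds.
    """
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown thresholding method {method!r}")
        ts = []
        for name, ch in (("ch1", pair.ch1), ("ch2", pair.ch2)):
            if np.ptp(ch) == 0:
                raise ValueError(
                    f"{name} is constant; Otsu thresholding is undefined -- "
                    "pass fixed thresholds instead"
                )
            ts.append(float(threshold_otsu(ch)))
        t1, t2 = ts
    else:
        t1, t2 = (float(method[0]), float(method[1]))
    masks = (pair.ch1 > t1, pair.ch2 > t2)
    return t1, t2, masks


def manders_overlap(
    pair: ImagePair,
    masks: tuple[np.ndarray, np.ndarray],
    thresholds: Optional[tuple[float, float]] = None,
) -> ColocResult:
    """Mander's coefficients over the union of the foreground masks.

    When ``thresholds`` are given, intensities are background-subtracted
    (``max(I - t, 0)``) before the sums, so pure-background pixels contribute
    nothing; without thresholds raw intensities are used.
    """
    m1_mask, m2_mask = masks
    if m1_mask.shape != pair.ch1.shape or m2_mask.shape != pair.ch1.shape:
        raise ValueError("masks must match image dimensions")
    union = m1_mask | m2_mask
    n_fg = int(union.sum())
    t1, t2 = thresholds if thresholds is not None else (0.0, 0.0)
    if n_fg == 0:
        return ColocResult(np.nan, np.nan, np.nan, (t1, t2), 0,
                           defined=False, reason="empty foreground")

    a = np.clip(pair.ch1 - t1, 0, None)
    b = np.clip(pair.ch2 - t2, 0, None)

    au, bu = a[union], b[union]
    denom = np.sqrt((au ** 2).sum() * (bu ** 2).sum())
    if denom == 0:
        return ColocResult(np.nan, np.nan, np.nan, (t1, t2), n_fg,
                           defined=False, reason="zero-intensity foreground")
    r = float((au * bu).sum() / denom)

    s1 = a[m1_mask].sum()
    s2 = b[m2_mask].sum()
    m1 = float(a[m2_mask].sum() / s1) if s1 > 0 else np.nan
    m2 = float(b[m1_mask].sum() / s2) if s2 > 0 else np.nan
    return ColocResult(r, m1, m2, (t1, t2), n_fg)
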