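"""Rotation-invariant uniform local binary patterns.

Three configurations — (P=8, R=1), (P=16, R=2), (P=24, R=3) — each yield a
normalized histogram over the P+2 rotation-invariant uniform codes (the last
bin pools the non-uniform patterns) plus six histogram summaries. The codes
come from :func:`skimage.feature.local_binary_pattern` (neighbor >= center
comparison, bilinear interpolation for off-grid neighbors).

Only pixels whose full interpolation support lies inside the region mask are
histogrammed: the mask is eroded with a disk of radius R+2 (interpolation at
radius R touches grid points up to ~R+sqrt(2) away), which also makes the
features exactly translation-invariant. A configuration whose eroded mask is
empty raises a region error and is skipped for that slice.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.feature import local_binary_pattern
from skimage.morphology import disk

from .glcm import RegionError, _entropy_bits
from .registry import LBP_CONFIGS


def lbp_histogram(values: np.ndarray, mask: np.ndarray, P: int, R: int) -> np.ndarray:
    """Normalized histogram of rotation-invariant uniform codes, P+2 bins."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=disk(R + 2))
    if not eroded.any():
        raise RegionError(f"mask empty after erosion for LBP P={P}, R={R}")
    with warnings.catch_warnings():
        # float input is intended: codes are histogrammed over in-mask pixels only
        warnings.simplefilter("ignore", UserWarning)
        codes = local_binary_pattern(values, P, R, method="uniform")
    counts = np.bincount(codes[eroded].astype(int), minlength=P + 2)
    return counts / counts.sum()


def lbp_summaries(hist: np.ndarray) -> np.ndarray:
    """Six summaries of the code distribution.

    Mean and sd are of the code value under the histogram; entropy (bits) and
    energy of the histogram itself; max bin height; and the non-uniform
    fraction (last bin).
    """
    b = np.arange(hist.size, dtype=float)
    mean = float((b * hist).sum())
    sd = float(np.sqrt(((b - mean) ** 2 * hist).sum()))
    return np.array(
        [
            mean,
            sd,
            _entropy_bits(hist),
            float((hist**2).sum()),
            float(hist.max()),
            float(hist[-1]),
        ]
    )


def lbp_features_slice(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """72 LBP features; NaN block for a configuration whose eroded mask is empty."""
    parts = []
    for P, R in LBP_CONFIGS:
        try:
            hist = lbp_histogram(values, mask, P, R)
        except RegionError:
            parts.append(np.full(P + 2 + 6, np.nan))
        else:
            parts.append(np.concatenate([hist, lbp_summaries(hist)]))
    return np.concatenate(parts)
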