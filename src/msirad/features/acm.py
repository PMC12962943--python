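"""Angle co-occurrence matrices: co-occurrence of gradient orientations.

Gradient orientation (Sobel 3x3, taken mod 180 degrees) is quantized into 8
angle bins. Pixels whose 3x3 neighborhood is not fully in-mask, or whose
gradient magnitude does not exceed a percentile threshold, are excluded. The
co-occurrence of angle bins at offsets (0,1) and (1,0) is accumulated
symmetrically and normalized, and six statistics are read off per matrix:
energy, entropy, contrast, homogeneity, correlation, dissimilarity —
6 stats x 2 offsets x 2 magnitude thresholds (25th, 50th in-mask percentile)
= 24 features. A threshold/offset with no valid pixel pair contributes six
zeros (logged convention).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .glcm import SENTINEL, RegionError, _entropy_bits, glcm
from .registry import ACM_MAG_PERCENTILES, ACM_OFFSETS, ACM_STAT_NAMES

logger = logging.getLogger(__name__)

N_ANGLE_BINS = 8


def gradient_orientation_bins(
    values: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel angle bin and magnitude; eligibility = 3x3 support in-mask."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RegionError("empty mask")
    gr = ndimage.sobel(values, axis=0, mode="nearest")
    gc = ndimage.sobel(values, axis=1, mode="nearest")
    magnitude = np.hypot(gr, gc)
    theta = np.mod(np.degrees(np.arctan2(gr, gc)), 180.0)
    bins = np.minimum((theta / (180.0 / N_ANGLE_BINS)).astype(int), N_ANGLE_BINS - 1)
    eligible = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    return bins, magnitude, eligible


def acm_stats(P: np.ndarray) -> dict[str, float]:
    """Six co-occurrence statistics of a normalized angle matrix."""
    n = P.shape[0]
    i = np.arange(n, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sd = float(np.sqrt(((i - mu) ** 2 * px).sum()))
    if sd > 0:
        correlation = float(((ii - mu) * (jj - mu) * P).sum() / sd**2)
    else:
        correlation = 0.0
    values = (
        float((P**2).sum()),
        _entropy_bits(P.ravel()),
        float(((ii - jj) ** 2 * P).sum()),
        float((P / (1.0 + (ii - jj) ** 2)).sum()),
        correlation,
        float((np.abs(ii - jj) * P).sum()),
    )
    return dict(zip(ACM_STAT_NAMES, values))


def acm_features_slice(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """24 angle co-occurrence features of one slice."""
    bins, magnitude, eligible = gradient_orientation_bins(values, mask)
    out = []
    for pct in ACM_MAG_PERCENTILES:
        if eligible.any():
            thr = np.percentile(magnitude[eligible], pct)
            above = eligible & (magnitude > thr)
        else:
            above = eligible
        labels = np.where(above, bins, SENTINEL).astype(np.int64)
        for off in ACM_OFFSETS:
            P = glcm(labels, N_ANGLE_BINS, off)
            if P is None:
                logger.debug(
                    "no above-threshold pixel pair (pct=%s, offset=%s); zeros", pct, off
                )
                out.append(np.zeros(len(ACM_STAT_NAMES)))
            else:
                stats = acm_stats(P)
                out.append(np.array([stats[s] for s in ACM_STAT_NAMES]))
    return np.concatenate(out)
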