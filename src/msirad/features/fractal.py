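"""Box-counting fractal dimension and lacunarity of thresholded binary sets.

For each of 16 equally spaced in-mask intensity thresholds, the slice is
binarized (intensity >= threshold, inside the mask) and three estimators are
computed on the resulting set:

* box-counting dimension of the set,
* box-counting dimension of its inner boundary,
* lacunarity — the coefficient of variation of box masses at one fixed scale.

The box grid is anchored at the mask's bounding box, which makes all three
estimators invariant to translating the region inside the image grid. An
empty thresholded set yields 0 for all three (deterministic convention).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .glcm import RegionError
from .registry import FD_N_THRESHOLDS

BOX_SIZES = (1, 2, 4, 8, 16)
LACUNARITY_BOX = 4


def _box_counts(binary: np.ndarray, size: int) -> np.ndarray:
    """Pixel mass per non-overlapping ``size``×``size`` box (padded grid)."""
    nr, nc = binary.shape
    pr = (-nr) % size
    pc = (-nc) % size
    if pr or pc:
        binary = np.pad(binary, ((0, pr), (0, pc)))
    nr, nc = binary.shape
    return (
        binary.reshape(nr // size, size, nc // size, size)
        .sum(axis=(1, 3))
        .astype(float)
    )


def box_counting_dimension(binary: np.ndarray, sizes=BOX_SIZES) -> float:
    """Slope of log N(s) vs log (1/s) over occupied-box counts, clipped to [0, 2]."""
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return 0.0
    usable = [s for s in sizes if s <= max(binary.shape)]
    counts = np.array([(_box_counts(binary, s) > 0).sum() for s in usable], dtype=float)
    if len(usable) < 2 or counts[0] == counts[-1]:
        return 0.0
    slope, _ = np.polyfit(np.log(usable), np.log(counts), 1)
    return float(np.clip(-slope, 0.0, 2.0))


def inner_boundary(binary: np.ndarray) -> np.ndarray:
    """Set pixels with at least one 4-neighbor outside the set."""
    eroded = ndimage.binary_erosion(
        binary, structure=ndimage.generate_binary_structure(2, 1)
    )
    return binary & ~eroded


def lacunarity(binary: np.ndarray, box: int = LACUNARITY_BOX) -> float:
    """Coefficient of variation (sd/mean) of box masses at one scale."""
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return 0.0
    masses = _box_counts(binary, box).ravel()
    mean = masses.mean()
    if mean == 0:
        return 0.0
    return float(masses.std(ddof=0) / mean)


def fd_thresholds(values: np.ndarray, mask: np.ndarray, n: int = FD_N_THRESHOLDS) -> np.ndarray:
    """``n`` equally spaced interior thresholds between in-mask min and max."""
    inside = values[mask]
    return np.linspace(inside.min(), inside.max(), n + 2)[1:-1]


def fd_features_slice(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """48 fractal features: (set dim, boundary dim, lacunarity) × 16 thresholds."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RegionError("empty mask")

    # Crop to the mask bounding box so the box grid travels with the region.
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    v = values[sl]
    m = mask[sl]

    out = np.zeros(3 * FD_N_THRESHOLDS)
    for k, t in enumerate(fd_thresholds(v, m)):
        s = m & (v >= t)
        if s.any():
            out[3 * k] = box_counting_dimension(s)
            out[3 * k + 1] = box_counting_dimension(inner_boundary(s))
            out[3 * k + 2] = lacunarity(s)
        # empty set -> all three stay 0 by convention
    return out
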