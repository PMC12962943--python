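"""Gray-level co-occurrence matrices and the 13 Haralick statistics.

The co-occurrence matrix is accumulated only over pixel pairs whose *both*
members lie inside the region mask, which is why the accumulation is done
here rather than through an off-the-shelf unmasked implementation.
"""

from __future__ import annotations

import numpy as np

from .registry import GLCM_STAT_NAMES

SENTINEL = -1

# Offsets (dr, dc) for the four planar directions at unit distance:
# 0 deg, 90 deg, 45 deg, 135 deg.
DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


class RegionError(ValueError):
    """Raised when a mask is empty or otherwise unusable for a feature."""


def quantize_slice(
    values: np.ndarray, mask: np.ndarray, levels: int
) -> tuple[np.ndarray, float, float]:
    """Equal-width quantization of in-mask intensities to ``levels`` gray levels.

    Returns ``(q, vmin, vmax)`` where ``q`` holds integer levels in
    ``[0, levels-1]`` inside the mask and :data:`SENTINEL` outside. A constant
    region maps entirely to level 0.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask shapes differ")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if not mask.any():
        raise RegionError("empty mask")

    inside = values[mask]
    vmin = float(inside.min())
    vmax = float(inside.max())
    q = np.full(values.shape, SENTINEL, dtype=np.int64)
    if vmax == vmin:
        q[mask] = 0
    else:
        scaled = (values[mask] - vmin) / (vmax - vmin) * levels
        q[mask] = np.clip(scaled.astype(np.int64), 0, levels - 1)
    return q, vmin, vmax


def glcm(q: np.ndarray, levels: int, offset: tuple[int, int]) -> np.ndarray | None:
    """Symmetric, normalized co-occurrence matrix at ``offset`` (dr, dc).

    A pair contributes only if both pixels are in-mask (non-sentinel); each
    pair is counted in both directions. Returns ``None`` when no valid pair
    exists at this offset.
    """
    dr, dc = offset
    nr, nc = q.shape
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    if r0 >= r1 or c0 >= c1:
        return None
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (a != SENTINEL) & (b != SENTINEL)
    if not valid.any():
        return None
    av = a[valid].astype(np.int64)
    bv = b[valid].astype(np.int64)
    counts = np.bincount(av * levels + bv, minlength=levels * levels).reshape(
        levels, levels
    )
    counts = counts + counts.T  # symmetric: count (i,j) and (j,i)
    return counts / counts.sum()


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_stats(P: np.ndarray) -> dict[str, float]:
    """The 13 classical Haralick statistics of a normalized GLCM.

    Entropies are in bits with the 0*log(0) := 0 convention; correlation and
    the information measures degrade gracefully (to 0) on degenerate
    matrices.
    """
    L = P.shape[0]
    i = np.arange(L, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    energy = float((P**2).sum())
    contrast = float(((ii - jj) ** 2 * P).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(((ii - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())

    # Sum / difference marginals p_{x+y}, p_{|x-y|}.
    ksum = np.arange(2 * L - 1, dtype=float)
    p_sum = np.bincount((ii + jj).astype(int).ravel(), weights=P.ravel(), minlength=2 * L - 1)
    kdiff = np.arange(L, dtype=float)
    p_diff = np.bincount(
        np.abs(ii - jj).astype(int).ravel(), weights=P.ravel(), minlength=L
    )

    sum_average = float((ksum * p_sum).sum())
    sum_variance = float(((ksum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy_bits(p_sum)
    entropy = _entropy_bits(P.ravel())
    diff_average = float((kdiff * p_diff).sum())
    difference_variance = float(((kdiff - diff_average) ** 2 * p_diff).sum())
    difference_entropy = _entropy_bits(p_diff)

    # Information measures of correlation.
    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    pxpy = np.outer(px, py)
    pos = pxpy > 0
    hxy1 = float(-(P[pos] * np.log2(pxpy[pos])).sum())
    hxy2 = float(-(pxpy[pos] * np.log2(pxpy[pos])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    values = (
        energy,
        contrast,
        correlation,
        variance,
        idm,
        sum_average,
        sum_variance,
        sum_entropy,
        entropy,
        difference_variance,
        difference_entropy,
        imc1,
        imc2,
    )
    return dict(zip(GLCM_STAT_NAMES, values))


def glcm_features_slice(
    values: np.ndarray, mask: np.ndarray, levels: int, distances=(1, 2, 3, 4)
) -> np.ndarray:
    """Direction-averaged Haralick statistics at each distance, one slice.

    Returns ``len(distances) * 13`` values in registry order; NaN for a
    distance with no valid pixel pair in any direction.
    """
    q, _, _ = quantize_slice(values, mask, levels)
    out = []
    for d in distances:
        per_dir = []
        for dr, dc in DIRECTIONS:
            P = glcm(q, levels, (dr * d, dc * d))
            if P is not None:
                stats = glcm_stats(P)
                per_dir.append([stats[s] for s in GLCM_STAT_NAMES])
        if per_dir:
            out.append(np.mean(per_dir, axis=0))
        else:
            out.append(np.full(len(GLCM_STAT_NAMES), np.nan))
    return np.concatenate(out)
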