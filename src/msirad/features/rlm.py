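"""Gray-level run-length statistics.

A run is a maximal collinear segment of in-mask pixels sharing one quantized
gray level. Gray levels are 1-based inside the low/high gray-level emphasis
statistics (a level-0 run must not carry infinite low-gray emphasis).
"""

from __future__ import annotations

import numpy as np

from .glcm import SENTINEL, RegionError, quantize_slice
from .registry import RLM_STAT_NAMES

RLM_DIRECTION_NAMES = ("0", "90", "45", "135")


def _lines(q: np.ndarray, direction: str):
    """Yield the 1D scan lines of ``q`` along a direction."""
    if direction == "0":
        yield from q
    elif direction == "90":
        yield from q.T
    elif direction == "45":
        # along (dr, dc) = (1, 1): diagonals
        for off in range(-(q.shape[0] - 1), q.shape[1]):
            yield np.diagonal(q, offset=off)
    elif direction == "135":
        qf = np.fliplr(q)
        for off in range(-(q.shape[0] - 1), q.shape[1]):
            yield np.diagonal(qf, offset=off)
    else:  # pragma: no cover
        raise ValueError(f"unknown direction {direction!r}")


def run_lengths(q: np.ndarray, direction: str) -> tuple[np.ndarray, np.ndarray]:
    """All (gray level, run length) pairs along ``direction``.

    Sentinel pixels break runs and contribute none.
    """
    levels = []
    lengths = []
    for line in _lines(q, direction):
        line = np.ascontiguousarray(line)
        n = line.size
        # Run boundaries wherever the value changes; runs of SENTINEL dropped.
        starts = np.flatnonzero(np.r_[True, line[1:] != line[:-1]])
        ends = np.r_[starts[1:], n]
        keep = line[starts] != SENTINEL
        levels.append(line[starts[keep]])
        lengths.append(ends[keep] - starts[keep])
    return (
        np.concatenate(levels).astype(float),
        np.concatenate(lengths).astype(float),
    )


def rlm_stats(levels: np.ndarray, lengths: np.ndarray, n_pixels: int) -> dict[str, float]:
    """The 11 run-length statistics from the list of runs."""
    if levels.size == 0:
        raise RegionError("no runs in region")
    n_r = levels.size
    g = levels + 1.0  # 1-based gray level
    l = lengths

    sre = float((1.0 / l**2).sum() / n_r)
    lre = float((l**2).sum() / n_r)

    # Gray-level and run-length non-uniformity need marginal counts.
    lvl_counts = np.bincount(levels.astype(int))
    gln = float((lvl_counts.astype(float) ** 2).sum() / n_r)
    len_counts = np.bincount(lengths.astype(int))
    rln = float((len_counts.astype(float) ** 2).sum() / n_r)

    rp = n_r / float(n_pixels)
    lgre = float((1.0 / g**2).sum() / n_r)
    hgre = float((g**2).sum() / n_r)
    srlge = float((1.0 / (g**2 * l**2)).sum() / n_r)
    srhge = float((g**2 / l**2).sum() / n_r)
    lrlge = float((l**2 / g**2).sum() / n_r)
    lrhge = float((g**2 * l**2).sum() / n_r)

    values = (sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge)
    return dict(zip(RLM_STAT_NAMES, values))


def rlm_features(q: np.ndarray, direction: str) -> dict[str, float]:
    """11 run-length statistics of a quantized slice along one direction."""
    n_pixels = int((q != SENTINEL).sum())
    if n_pixels == 0:
        raise RegionError("empty region")
    levels, lengths = run_lengths(q, direction)
    return rlm_stats(levels, lengths, n_pixels)


def rlm_features_slice(
    values: np.ndarray, mask: np.ndarray, level_set=(8, 16, 32, 64)
) -> np.ndarray:
    """Direction-averaged run-length statistics at each quantization depth.

    Returns ``len(level_set) * 11`` values in registry order.
    """
    out = []
    for levels in level_set:
        q, _, _ = quantize_slice(values, mask, levels)
        per_dir = []
        for d in RLM_DIRECTION_NAMES:
            stats = rlm_features(q, d)
            per_dir.append([stats[s] for s in RLM_STAT_NAMES])
        out.append(np.mean(per_dir, axis=0))
    return np.concatenate(out)
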