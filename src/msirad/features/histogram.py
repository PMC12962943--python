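"""First-order intensity-histogram statistics of the in-mask voxels."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .glcm import RegionError, _entropy_bits
from .registry import HIST_STAT_NAMES

ENTROPY_BINS = 32


def histogram_stats(values: np.ndarray, mask: np.ndarray | None = None) -> dict[str, float]:
    """14 first-order statistics of the masked intensities.

    A constant region has sd, skewness, kurtosis (excess) and entropy 0 by
    convention. Entropy is computed from a 32-bin equal-width histogram
    between the in-mask min and max, in bits. ``energy`` is the mean squared
    intensity.
    """
    values = np.asarray(values, dtype=float)
    x = values[np.asarray(mask, dtype=bool)] if mask is not None else values.ravel()
    if x.size == 0:
        raise RegionError("empty region")

    vmin = float(x.min())
    vmax = float(x.max())
    sd = float(x.std(ddof=0))
    if sd > 0:
        skew = float(sps.skew(x, bias=True))
        kurt = float(sps.kurtosis(x, fisher=True, bias=True))
        counts, _ = np.histogram(x, bins=ENTROPY_BINS, range=(vmin, vmax))
        entropy = _entropy_bits(counts / counts.sum())
    else:
        skew = kurt = entropy = 0.0

    values_out = (
        float(x.mean()),
        sd,
        skew,
        kurt,
        float(np.median(x)),
        vmin,
        vmax,
        vmax - vmin,
        float((x**2).mean()),
        entropy,
        float(np.percentile(x, 10)),
        float(np.percentile(x, 25)),
        float(np.percentile(x, 75)),
        float(np.percentile(x, 90)),
    )
    return dict(zip(HIST_STAT_NAMES, values_out))


def histogram_features_slice(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    stats = histogram_stats(values, mask)
    return np.array([stats[s] for s in HIST_STAT_NAMES])
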