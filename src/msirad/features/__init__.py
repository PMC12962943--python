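"""Slice-wise texture feature extraction over segmented regions.

Features are computed independently on every eligible axial slice (a slice is
eligible when the region mask covers at least ``min_pixels`` pixels there) and
averaged, unweighted, into a single value per feature. Directional families
(GLCM, RLM) are averaged over the four planar directions before the slice
average. A slice on which a feature's own precondition fails (e.g. the eroded
mask of an LBP configuration is empty) is skipped for that feature only.
"""

from __future__ import annotations

import logging
from typing import TYPE_CHECKING

import numpy as np

from .acm import acm_features_slice
from .fractal import fd_features_slice
from .glcm import RegionError, glcm_features_slice, quantize_slice
from .histogram import histogram_features_slice
from .lbp import lbp_features_slice
from .registry import DEFAULT_REGISTRY, N_FEATURES, FeatureRegistry
from .rlm import rlm_features_slice

if TYPE_CHECKING:  # pragma: no cover
    from ..cohort_io import VolumeCase

logger = logging.getLogger(__name__)

MIN_SLICE_PIXELS = 16
GLCM_QUANT_LEVELS = 32

__all__ = [
    "DEFAULT_REGISTRY",
    "FeatureRegistry",
    "N_FEATURES",
    "RegionError",
    "quantize_slice",
    "slice_features",
    "extract_region_features",
    "extract_cohort",
    "MIN_SLICE_PIXELS",
]


def _crop_to_mask(values: np.ndarray, mask: np.ndarray):
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return values[sl], mask[sl]


def slice_features(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """All 254 features of one axial slice, NaN where a precondition fails."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RegionError("empty slice mask")
    v, m = _crop_to_mask(values, mask)

    parts = []
    for fn in (
        lambda: glcm_features_slice(v, m, GLCM_QUANT_LEVELS),
        lambda: histogram_features_slice(v, m),
        lambda: rlm_features_slice(v, m),
        lambda: fd_features_slice(v, m),
        lambda: lbp_features_slice(v, m),
        lambda: acm_features_slice(v, m),
    ):
        parts.append(fn())
    vec = np.concatenate(parts)
    if vec.size != N_FEATURES:  # pragma: no cover - registry/implementation guard
        raise RuntimeError("slice feature vector length mismatch")
    return vec


def extract_region_features(
    case: "VolumeCase",
    region: str,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
    min_pixels: int = MIN_SLICE_PIXELS,
) -> np.ndarray:
    """254-vector of slice-averaged features for one region of one case.

    Parameters
    ----------
    case:
        Volume with aligned binary tumor and pancreas masks.
    region:
        ``"tumor"`` or ``"pancreas"``.
    min_pixels:
        Slice eligibility floor: slices with fewer in-mask pixels are ignored
        entirely (texture matrices are meaningless on a handful of pixels).
    """
    if region == "tumor":
        mask3 = case.tumor_mask
    elif region == "pancreas":
        mask3 = case.pancreas_mask
    else:
        raise ValueError(f"unknown region {region!r}")

    per_slice = []
    for k in range(case.intensities.shape[2]):
        m = mask3[:, :, k].astype(bool)
        if m.sum() >= min_pixels:
            per_slice.append(slice_features(case.intensities[:, :, k], m))
    if not per_slice:
        raise RegionError(f"case {case.case_id}: no eligible {region} slice")

    stacked = np.vstack(per_slice)
    with np.errstate(invalid="ignore"):
        averaged = np.nanmean(stacked, axis=0)
    missing = ~np.isfinite(averaged)
    if missing.any():
        names = [registry.names[i] for i in np.flatnonzero(missing)]
        logger.warning(
            "case %s region %s: no eligible slice for %d feature(s) %s; set to 0",
            case.case_id,
            region,
            len(names),
            names[:5],
        )
        averaged[missing] = 0.0
    return averaged


def extract_cohort(
    cases,
    region: str,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
    min_pixels: int = MIN_SLICE_PIXELS,
):
    """Feature table (cases × 254) for one region over an iterable of cases."""
    from ..cohort_io import FeatureTable

    case_ids = []
    rows = []
    for case in cases:
        case_ids.append(case.case_id)
        rows.append(extract_region_features(case, region, registry, min_pixels))
    return FeatureTable(
        region=region,
        feature_names=list(registry.names),
        values=np.vstack(rows),
        case_ids=case_ids,
    )
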