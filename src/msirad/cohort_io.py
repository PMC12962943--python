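"""Cohort loading, validation and serialization.

A cohort is a CSV manifest (``case_id,label,volume,tumor_mask,pancreas_mask``)
pointing at per-case NIfTI volumes and segmentation masks. The positive class
is ``MSI-H``; everything is validated at load time — malformed manifests,
multi-label masks and shape mismatches are errors, never silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .features.registry import DEFAULT_REGISTRY, FeatureRegistry

POSITIVE_LABEL = "MSI-H"
CONTROL_LABEL = "control"
MANIFEST_COLUMNS = ("case_id", "label", "volume", "tumor_mask", "pancreas_mask")


class ManifestFormatError(ValueError):
    """Malformed manifest: missing column, duplicate id, unknown label."""


class GeometryError(ValueError):
    """Volume/mask shape disagreement or invalid mask content."""


@dataclass
class VolumeCase:
    """One patient's CT volume and its two aligned binary segmentations.

    Axial slices lie along the third array axis. Voxel spacing is carried for
    bookkeeping only — the texture features are defined on the pixel grid.
    """

    case_id: str
    label: int  # 1 = MSI-H, 0 = control
    intensities: np.ndarray
    tumor_mask: np.ndarray
    pancreas_mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not (
            self.intensities.shape == self.tumor_mask.shape == self.pancreas_mask.shape
        ):
            raise GeometryError(f"case {self.case_id}: array shapes differ")
        for name, m in (("tumor", self.tumor_mask), ("pancreas", self.pancreas_mask)):
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise GeometryError(f"case {self.case_id}: {name} mask is not binary")
            if not m.any():
                raise GeometryError(f"case {self.case_id}: {name} mask is empty")


@dataclass
class FeatureTable:
    """Cases × features matrix for one region, columns in registry order."""

    region: str
    feature_names: list[str]
    values: np.ndarray
    case_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.case_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape disagrees with names/ids")

    def validate_against(self, registry: FeatureRegistry = DEFAULT_REGISTRY) -> None:
        if self.feature_names != registry.names:
            missing = [n for n in registry.names if n not in self.feature_names]
            extra = [n for n in self.feature_names if n not in registry.names]
            raise ManifestFormatError(
                f"feature columns disagree with registry "
                f"(missing {missing[:5]}, unexpected {extra[:5]})"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("feature table contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "case_id", self.case_ids)
        return df


def parse_label(raw: str) -> int:
    s = str(raw).strip()
    if s == POSITIVE_LABEL:
        return 1
    if s == CONTROL_LABEL:
        return 0
    raise ManifestFormatError(f"unknown label {raw!r} (expected MSI-H or control)")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a cohort manifest.

    Returns a DataFrame with the five manifest columns plus a binary ``y``
    column (1 = MSI-H).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ManifestFormatError(f"{path}: empty manifest") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestFormatError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ManifestFormatError(f"{path}: manifest has no rows")
    dupes = df["case_id"][df["case_id"].duplicated()].tolist()
    if dupes:
        raise ManifestFormatError(f"{path}: duplicate case_id {dupes}")
    df = df.copy()
    df["y"] = [parse_label(v) for v in df["label"]]
    return df


def _read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def load_case(row) -> VolumeCase:
    """Load one manifest row into a validated :class:`VolumeCase`.

    Masks are binarized on load (any nonzero voxel becomes 1); mask files with
    more than one nonzero value are rejected as multi-label.
    """
    vol, spacing = _read_nifti(row["volume"])
    masks = {}
    for key in ("tumor_mask", "pancreas_mask"):
        m, _ = _read_nifti(row[key])
        if m.shape != vol.shape:
            raise GeometryError(
                f"case {row['case_id']}: {key} shape {m.shape} != volume {vol.shape}"
            )
        nonzero = np.unique(m[m != 0])
        if nonzero.size > 1:
            raise GeometryError(
                f"case {row['case_id']}: {key} is multi-label ({nonzero.size} values)"
            )
        masks[key] = (m != 0).astype(np.uint8)
    return VolumeCase(
        case_id=str(row["case_id"]),
        label=int(row["y"]) if "y" in row else parse_label(row["label"]),
        intensities=vol,
        tumor_mask=masks["tumor_mask"],
        pancreas_mask=masks["pancreas_mask"],
        spacing=spacing,
    )


def load_cohort(manifest_path: str | Path):
    """Manifest + all cases, in manifest order. Returns (manifest, cases)."""
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    cases = []
    for _, row in manifest.iterrows():
        resolved = row.copy()
        for key in ("volume", "tumor_mask", "pancreas_mask"):
            p = Path(row[key])
            resolved[key] = p if p.is_absolute() else base / p
        cases.append(load_case(resolved))
    return manifest, cases


def save_nifti(
    data: np.ndarray, path: str | Path, spacing: tuple[float, float, float] = (1, 1, 1)
) -> None:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """CSV serialization with full float precision (lossless round-trip)."""
    df = table.to_frame()
    df.insert(0, "region", table.region)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(
    path: str | Path, registry: FeatureRegistry = DEFAULT_REGISTRY
) -> FeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("region", "case_id"):
        if col not in df.columns:
            raise ManifestFormatError(f"{path}: missing column {col!r}")
    names = [c for c in df.columns if c not in ("region", "case_id")]
    table = FeatureTable(
        region=str(df["region"].iloc[0]),
        feature_names=names,
        values=df[names].to_numpy(dtype=float),
        case_ids=df["case_id"].astype(str).tolist(),
    )
    table.validate_against(registry)
    return table
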