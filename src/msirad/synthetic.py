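"""Synthetic phantom cohorts with class-conditional texture heterogeneity.

Real cohorts of MSI-H vs MSI-stable pancreatic ductal adenocarcinoma CT scans
are not publicly available, so every downstream stage is exercised on phantom
volumes: a pancreas ellipsoid at a base intensity containing a darker tumor
ellipsoid, with stationary Gaussian-random-field texture added inside each
region. The class signal is planted as a *heterogeneity* difference — the
positive class gets a different texture amplitude (sigma) and correlation
length in the configured effect regions — not as a mean-intensity shift,
mirroring the texture-feature character of the discrimination task.

Everything is a pure function of (config, seed): per-case seeds are derived
deterministically from the master seed by case index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort_io import (
    CONTROL_LABEL,
    MANIFEST_COLUMNS,
    POSITIVE_LABEL,
    VolumeCase,
    save_nifti,
)

TUMOR_OFFSET = -20.0  # tumor rests at base_intensity + offset
BACKGROUND_NOISE_SIGMA = 2.0  # mild global acquisition-like noise


class PhantomParameterError(ValueError):
    pass


class PhantomGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings for one phantom cohort.

    The default cohort design matches the study design the pipeline targets:
    19 positive cases vs 76 controls (1:4), small axial volumes. Texture
    parameters are in arbitrary CT-like units; ``effect_regions`` lists the
    regions in which the positive class receives the *case* texture
    parameters (empty = null cohort, label carries no signal).
    """

    n_cases: int = 19
    n_controls: int = 76
    volume_shape: tuple[int, int, int] = (64, 64, 12)
    pancreas_axes: tuple[float, float, float] = (24.0, 18.0, 5.0)
    tumor_axes: tuple[float, float, float] = (10.0, 8.0, 3.0)
    base_intensity: float = 100.0
    texture_sigma_case: float = 30.0
    texture_sigma_control: float = 10.0
    corr_length_case: float = 1.5
    corr_length_control: float = 3.0
    effect_regions: tuple[str, ...] = ("tumor", "pancreas")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise PhantomParameterError("both classes must be nonempty")
        if any(s < 1 for s in self.volume_shape):
            raise PhantomParameterError("volume_shape entries must be positive")
        if not all(t < p for t, p in zip(self.tumor_axes, self.pancreas_axes)):
            raise PhantomGeometryError(
                "tumor ellipsoid must be strictly contained in the pancreas ellipsoid"
            )
        limit = min(self.volume_shape) / 2
        for cl in (self.corr_length_case, self.corr_length_control):
            if not 0 < cl < limit:
                raise PhantomParameterError(
                    f"correlation lengths must lie in (0, {limit}) voxels"
                )
        for s in (self.texture_sigma_case, self.texture_sigma_control):
            if s < 0:
                raise PhantomParameterError("texture sigmas must be nonnegative")
        unknown = set(self.effect_regions) - {"tumor", "pancreas"}
        if unknown:
            raise PhantomParameterError(f"unknown effect regions {sorted(unknown)}")


def null_config(**overrides) -> PhantomConfig:
    """No-effect cohort: the label carries no texture signal."""
    overrides.setdefault("effect_regions", ())
    return PhantomConfig(**overrides)


def strong_effect_config(**overrides) -> PhantomConfig:
    """Strong heterogeneity difference planted in both regions (the default)."""
    overrides.setdefault("effect_regions", ("tumor", "pancreas"))
    return PhantomConfig(**overrides)


@dataclass
class PhantomCohort:
    """Manifest plus the realized per-case generation parameters."""

    manifest: pd.DataFrame
    manifest_path: Path
    generation_log: list[dict] = field(default_factory=list)


def gaussian_random_field(
    shape: tuple[int, int], corr_length: float, sigma: float, seed: int
) -> np.ndarray:
    """Stationary 2D Gaussian random field.

    White noise convolved with a Gaussian kernel of width ``corr_length``
    (voxels), then recentred to zero mean and rescaled to standard deviation
    ``sigma``. Deterministic given ``seed``.
    """
    if corr_length <= 0:
        raise PhantomParameterError("corr_length must be positive")
    if sigma < 0:
        raise PhantomParameterError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    if sigma == 0:
        return np.zeros(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=corr_length, mode="reflect")
    smooth -= smooth.mean()
    sd = smooth.std(ddof=0)
    if sd == 0:  # pragma: no cover - degenerate 1x1 grids
        return np.zeros(shape)
    return smooth * (sigma / sd)


def _ellipsoid_mask(shape, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    center = [(s - 1) / 2 for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return (r2 <= 1.0).astype(np.uint8)


def _region_params(config: PhantomConfig, region: str, label: int):
    if label == 1 and region in config.effect_regions:
        return config.texture_sigma_case, config.corr_length_case
    return config.texture_sigma_control, config.corr_length_control


def make_phantom_case(
    config: PhantomConfig, label: int, case_seed: int, case_id: str = "case"
) -> tuple[VolumeCase, dict]:
    """One phantom volume with tumor/pancreas masks and planted texture.

    Texture is an independent 2D Gaussian random field per axial slice per
    region (the feature extraction is slice-wise 2D); the pancreas field is
    applied outside the tumor so each region's texture is governed by its own
    parameters. Returns the case and a log entry of the realized parameters.
    """
    shape = config.volume_shape
    rng = np.random.default_rng(np.random.SeedSequence(case_seed))

    pancreas = _ellipsoid_mask(shape, config.pancreas_axes)
    tumor = _ellipsoid_mask(shape, config.tumor_axes)
    if not (tumor <= pancreas).all():  # pragma: no cover - config guard
        raise PhantomGeometryError("tumor mask escapes the pancreas mask")

    volume = rng.normal(0.0, BACKGROUND_NOISE_SIGMA, size=shape)
    volume[pancreas == 1] += config.base_intensity
    volume[tumor == 1] += TUMOR_OFFSET

    log = {"case_id": case_id, "label": int(label), "seed": int(case_seed)}
    shell = pancreas.astype(bool) & ~tumor.astype(bool)
    for region, region_mask in (("pancreas", shell), ("tumor", tumor.astype(bool))):
        sigma, corr = _region_params(config, region, label)
        log[f"{region}_sigma"] = sigma
        log[f"{region}_corr_length"] = corr
        for k in range(shape[2]):
            m = region_mask[:, :, k]
            if not m.any():
                continue
            grf_seed = int(rng.integers(2**31))
            fld = gaussian_random_field(shape[:2], corr, sigma, grf_seed)
            volume[:, :, k][m] += fld[m]

    case = VolumeCase(
        case_id=case_id,
        label=int(label),
        intensities=volume,
        tumor_mask=tumor,
        pancreas_mask=pancreas,
    )
    return case, log


def case_seed_for(config: PhantomConfig, index: int) -> int:
    """Per-case seed, a pure function of (master seed, case index)."""
    return int(np.random.SeedSequence([config.seed, index]).generate_state(1)[0] & 0x7FFFFFFF)


def iter_cases(config: PhantomConfig):
    """Yield (case, log) for the whole cohort, positives first, in-memory."""
    labels = [1] * config.n_cases + [0] * config.n_controls
    for idx, label in enumerate(labels):
        prefix = "msi" if label == 1 else "ctl"
        case_id = f"{prefix}{idx:03d}"
        yield make_phantom_case(config, label, case_seed_for(config, idx), case_id)


def generate_cohort(config: PhantomConfig, out_dir: str | Path) -> PhantomCohort:
    """Write the full cohort (volumes, masks, manifest, config, log) to disk."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "volumes").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    rows = []
    logs = []
    for case, log in iter_cases(config):
        paths = {
            "volume": f"volumes/{case.case_id}_vol.nii.gz",
            "tumor_mask": f"volumes/{case.case_id}_tumor.nii.gz",
            "pancreas_mask": f"volumes/{case.case_id}_pancreas.nii.gz",
        }
        save_nifti(case.intensities, out_dir / paths["volume"])
        save_nifti(case.tumor_mask, out_dir / paths["tumor_mask"])
        save_nifti(case.pancreas_mask, out_dir / paths["pancreas_mask"])
        rows.append(
            {
                "case_id": case.case_id,
                "label": POSITIVE_LABEL if case.label == 1 else CONTROL_LABEL,
                **paths,
            }
        )
        logs.append(log)

    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    cfg = asdict(config)
    cfg["effect_regions"] = list(config.effect_regions)
    (out_dir / "config.json").write_text(json.dumps(cfg, indent=2))
    (out_dir / "generation_log.json").write_text(json.dumps(logs, indent=2))
    return PhantomCohort(manifest=manifest, manifest_path=manifest_path, generation_log=logs)
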