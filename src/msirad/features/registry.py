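"""Registry of the 254 texture features computed per region.

Six families quantify complementary aspects of the segmented region on each
axial slice:

* ``GLCM`` — 13 Haralick statistics of the gray-level co-occurrence matrix,
  at 4 pixel distances (1–4), each averaged over the 4 planar directions
  (52 features).
* ``HIST`` — 14 first-order intensity-histogram statistics.
* ``RLM``  — 11 gray-level run-length statistics at 4 quantization depths
  (8, 16, 32, 64 levels), each averaged over the 4 directions (44 features).
* ``FD``   — box-counting fractal dimension of the thresholded set, of its
  boundary, and lacunarity, at 16 equally spaced in-mask intensity
  thresholds (48 features).
* ``LBP``  — rotation-invariant uniform local-binary-pattern histograms for
  (P=8,R=1), (P=16,R=2), (P=24,R=3) plus 6 histogram summaries per
  configuration (72 features).
* ``ACM``  — angle co-occurrence of Sobel gradient orientations: 6 matrix
  statistics × 2 offsets × 2 magnitude-percentile thresholds (24 features).

Feature names are ``<FAMILY><index>`` with a 1-based per-family index; the
registry order is the canonical column order of every feature table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GLCM_STAT_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

HIST_STAT_NAMES = (
    "mean",
    "sd",
    "skewness",
    "kurtosis",
    "median",
    "min",
    "max",
    "range",
    "energy",
    "entropy",
    "p10",
    "p25",
    "p75",
    "p90",
)

RLM_STAT_NAMES = (
    "SRE",
    "LRE",
    "GLN",
    "RLN",
    "RP",
    "LGRE",
    "HGRE",
    "SRLGE",
    "SRHGE",
    "LRLGE",
    "LRHGE",
)

ACM_STAT_NAMES = (
    "energy",
    "entropy",
    "contrast",
    "homogeneity",
    "correlation",
    "dissimilarity",
)

FD_ESTIMATOR_NAMES = ("set_dimension", "boundary_dimension", "lacunarity")

GLCM_DISTANCES = (1, 2, 3, 4)
RLM_LEVELS = (8, 16, 32, 64)
FD_N_THRESHOLDS = 16
LBP_CONFIGS = ((8, 1), (16, 2), (24, 3))
LBP_SUMMARY_NAMES = (
    "hist_mean",
    "hist_sd",
    "hist_entropy",
    "hist_energy",
    "hist_max",
    "frac_nonuniform",
)
ACM_OFFSETS = ((0, 1), (1, 0))
ACM_MAG_PERCENTILES = (25, 50)

FAMILY_SIZES = {"GLCM": 52, "HIST": 14, "RLM": 44, "FD": 48, "LBP": 72, "ACM": 24}
N_FEATURES = 254


@dataclass(frozen=True)
class FeatureDescriptor:
    """One registry entry: a name, its family, and its parameterization."""

    name: str
    family: str
    params: dict = field(default_factory=dict)


def _build_descriptors() -> tuple[FeatureDescriptor, ...]:
    out: list[FeatureDescriptor] = []

    idx = 0
    for d in GLCM_DISTANCES:
        for stat in GLCM_STAT_NAMES:
            idx += 1
            out.append(
                FeatureDescriptor(f"GLCM{idx}", "GLCM", {"distance": d, "stat": stat})
            )

    for i, stat in enumerate(HIST_STAT_NAMES, start=1):
        out.append(FeatureDescriptor(f"HIST{i}", "HIST", {"stat": stat}))

    idx = 0
    for levels in RLM_LEVELS:
        for stat in RLM_STAT_NAMES:
            idx += 1
            out.append(
                FeatureDescriptor(f"RLM{idx}", "RLM", {"levels": levels, "stat": stat})
            )

    idx = 0
    for k in range(1, FD_N_THRESHOLDS + 1):
        for est in FD_ESTIMATOR_NAMES:
            idx += 1
            out.append(
                FeatureDescriptor(f"FD{idx}", "FD", {"threshold_index": k, "estimator": est})
            )

    idx = 0
    for p, r in LBP_CONFIGS:
        for b in range(p + 2):
            idx += 1
            out.append(
                FeatureDescriptor(f"LBP{idx}", "LBP", {"P": p, "R": r, "bin": b})
            )
        for stat in LBP_SUMMARY_NAMES:
            idx += 1
            out.append(
                FeatureDescriptor(f"LBP{idx}", "LBP", {"P": p, "R": r, "stat": stat})
            )

    idx = 0
    for pct in ACM_MAG_PERCENTILES:
        for off in ACM_OFFSETS:
            for stat in ACM_STAT_NAMES:
                idx += 1
                out.append(
                    FeatureDescriptor(
                        f"ACM{idx}",
                        "ACM",
                        {"magnitude_percentile": pct, "offset": off, "stat": stat},
                    )
                )

    return tuple(out)


class FeatureRegistry:
    """Ordered collection of the 254 feature descriptors.

    The default registry is the canonical one; its order defines the column
    order of every :class:`~msirad.cohort_io.FeatureTable`.
    """

    version = "1.0"

    def __init__(self) -> None:
        self.descriptors = _build_descriptors()
        self._by_name = {d.name: d for d in self.descriptors}
        if len(self.descriptors) != N_FEATURES:  # pragma: no cover - construction guard
            raise RuntimeError("registry must contain exactly 254 features")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def __len__(self) -> int:
        return len(self.descriptors)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> FeatureDescriptor:
        return self._by_name[name]

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.descriptors:
            counts[d.family] = counts.get(d.family, 0) + 1
        return counts

    def to_json_dict(self) -> dict:
        return {
            "version": self.version,
            "n_features": len(self),
            "features": [
                {"name": d.name, "family": d.family, "params": _jsonable(d.params)}
                for d in self.descriptors
            ],
        }


def _jsonable(params: dict) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()}


DEFAULT_REGISTRY = FeatureRegistry()
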