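"""Shared fixtures: small phantom cohorts and their feature tables.

The small cohort trades cohort size and volume size down so unit tests stay
fast; the full-size study conditions are exercised in the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from msirad.features import extract_cohort
from msirad.synthetic import PhantomConfig, iter_cases


def small_config(**overrides) -> PhantomConfig:
    defaults = dict(
        n_cases=6,
        n_controls=12,
        volume_shape=(48, 48, 8),
        pancreas_axes=(18.0, 14.0, 3.0),
        tumor_axes=(8.0, 6.0, 2.0),
        texture_sigma_case=30.0,
        texture_sigma_control=10.0,
        corr_length_case=1.5,
        corr_length_control=3.0,
        seed=11,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def small_effect_cohort():
    cfg = small_config(effect_regions=("tumor", "pancreas"))
    cases = [c for c, _ in iter_cases(cfg)]
    labels = np.array([c.label for c in cases])
    return cfg, cases, labels


@pytest.fixture(scope="session")
def small_tables(small_effect_cohort):
    _, cases, labels = small_effect_cohort
    tumor = extract_cohort(cases, "tumor")
    pancreas = extract_cohort(cases, "pancreas")
    return tumor, pancreas, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
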