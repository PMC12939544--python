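"""Shared fixtures. Heavy cohorts are session-scoped and built lazily."""

from __future__ import annotations

import numpy as np
import pytest

from eegaffect.features import build_feature_matrix
from eegaffect.synth import (
    DEPRESSION_PRESET,
    NEGATIVE_EMOTION_PRESET,
    generate_cohort,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_cohort():
    """40 + 40 epochs with the default class presets."""
    return generate_cohort(40, DEPRESSION_PRESET, NEGATIVE_EMOTION_PRESET, seed=11)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Feature matrix of the small cohort (80 x 24)."""
    return build_feature_matrix(small_cohort)


@pytest.fixture(scope="session")
def medium_features():
    """100/class feature matrix used by the screening-pattern tests."""
    cohort = generate_cohort(
        100, DEPRESSION_PRESET, NEGATIVE_EMOTION_PRESET, seed=77
    )
    return build_feature_matrix(cohort)


@pytest.fixture(scope="session")
def benchmark_features():
    """The full default benchmark: 510 epochs per class (1020 x 24)."""
    from eegaffect.synth import default_cohort

    X, y = build_feature_matrix(default_cohort(510, seed=0))
    return X, y


@pytest.fixture(scope="session")
def null_benchmark_features():
    """Zero-class-gap cohort at the same size (labels carry no signal)."""
    from eegaffect.synth import null_cohort

    X, y = build_feature_matrix(null_cohort(510, seed=0))
    return X, y
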