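"""Shared fixtures: synthetic cohorts at the study's group sizes.

The two full-size cohorts (strong-effect and zero-effect, 94 subjects,
16 channels) feed the end-to-end classification checks and are expensive
to build, so they are session-scoped and computed once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from erpemd.cohort import CohortSpec, EffectSpec, generate_cohort

settings.register_profile("fixed", derandomize=True)
settings.load_profile("fixed")
from erpemd.pipeline import features_from_cohort


def study_spec(effect: EffectSpec, seed: int, **overrides) -> CohortSpec:
    """Study conditions for the end-to-end runs: the final-sample group
    sizes (44/33/17), 16 channels, 20 expected trials, unit trial noise."""
    kwargs = dict(
        n_control=44,
        n_hr_noasd=33,
        n_hr_asd=17,
        n_channels=16,
        trials_mean=20.0,
        noise_sd=1.0,
        effect=effect,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


@pytest.fixture(scope="session")
def strong_features():
    """(table, labels) for a cohort with large, separable group effects."""
    cohort = generate_cohort(study_spec(EffectSpec.strong(), seed=11))
    table, labels, _log = features_from_cohort(cohort)
    return table, labels


@pytest.fixture(scope="session")
def null_features():
    """(table, labels) for a cohort with no group differences at all."""
    cohort = generate_cohort(study_spec(EffectSpec.null(), seed=12))
    table, labels, _log = features_from_cohort(cohort)
    return table, labels


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, cheap cohort for structural and pipeline tests."""
    spec = CohortSpec(
        n_control=4,
        n_hr_noasd=3,
        n_hr_asd=2,
        n_channels=4,
        trials_mean=12.0,
        noise_sd=0.5,
        effect=EffectSpec.strong(),
        seed=5,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
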