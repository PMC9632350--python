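"""Shared fixtures: one default synthetic cohort and one trained pipeline.

Training the full pipeline takes a few seconds, so it is done once per
session and reused by the correction, inspection and acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

import tractage as ta

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_config() -> ta.GeneratorConfig:
    return ta.GeneratorConfig(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return ta.generate_cohort(default_config)


@pytest.fixture(scope="session")
def trained(default_cohort) -> ta.TrainedPipeline:
    return ta.train_pipeline(default_cohort, seed=COHORT_SEED, fast=True)


@pytest.fixture(scope="session")
def corrected_test_set(trained):
    """(ann_corrected, linear_corrected, per-subject log) for the test set."""
    return trained.correct_test_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
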