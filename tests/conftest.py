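"""Shared fixtures: synthetic studies and their extracted feature matrices.

The expensive artefacts (the full two-class recovery study and its t = 1 s
feature matrix) are session-scoped so the end-to-end tests share one
computation.
"""

import numpy as np
import pytest

from dbfn.experiments import extract_study_features
from dbfn.synthetic_data import two_class_fixture

#: Seed of the shipped recovery fixture; recorded so every end-to-end number
#: in the suite is reproducible.
FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_study():
    """The standard recovery study: 6 subjects x 20 trials x 16 channels."""
    return two_class_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_feats_t1(fixture_study):
    return extract_study_features(fixture_study, window_s=1.0)


@pytest.fixture(scope="session")
def fixture_feats_static(fixture_study):
    return extract_study_features(fixture_study, window_s=60.0)


@pytest.fixture(scope="session")
def small_study():
    """A cheap study for protocol mechanics: 3 subjects x 8 trials x 8 ch."""
    return two_class_fixture(seed=3, n_subjects=3, n_trials=8, n_channels=8)


@pytest.fixture(scope="session")
def small_feats(small_study):
    """Small-study features at t = 10 s (6 windows per signal)."""
    return extract_study_features(small_study, window_s=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
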