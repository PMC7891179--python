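import numpy as np
import pytest

from oculomet import (
    DetectionParams,
    SynthesisParams,
    generate_cohort,
    load_group_profiles,
)
from oculomet.oculometrics import aggregate_subject, analyze_trial


@pytest.fixture(scope="session")
def profiles():
    return load_group_profiles("default")


@pytest.fixture(scope="session")
def detection():
    return DetectionParams()


@pytest.fixture(scope="session")
def small_cohort(profiles):
    """A small four-group cohort with traces (4/4/4/2 subjects)."""
    return generate_cohort(profiles, (4, 4, 4, 2), seed=20260, params=SynthesisParams())


@pytest.fixture(scope="session")
def small_features(small_cohort, detection):
    """Extracted feature dicts paired with their truth oracles."""
    records, truths = small_cohort
    rows = []
    for rec, truth in zip(records, truths):
        metrics = [
            analyze_trial(tr, detection)
            for trials in rec.recordings.values()
            for tr in trials
        ]
        rows.append((aggregate_subject(metrics), truth.feature_means(), rec))
    return rows


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
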