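import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from afbnp.cohort import CohortConfig
from afbnp.features import FeatureStandardizer
from afbnp.workflow import extract_cohort


#: Extraction settings for short synthetic recordings (the quality gate's
#: 48 h default is a study-scale constraint; these cohorts are scaled down).
SHORT_EXTRACT = {"enforce_quality": False}


@pytest.fixture(scope="session")
def small_cohort():
    """Eight patients with half-day recordings, feature-extracted."""
    cfg = CohortConfig(
        n_patients=8, recording_days_range=(0.5, 0.6), seed=11
    )
    return extract_cohort(config=cfg, **SHORT_EXTRACT)


@pytest.fixture(scope="session")
def small_standardizer(small_cohort):
    return FeatureStandardizer(groups=("CM", "RR", "HRV72h", "HRV30min")).fit(
        small_cohort
    )


@pytest.fixture(scope="session")
def small_tensors(small_cohort, small_standardizer):
    return [small_standardizer.transform(p) for p in small_cohort]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
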