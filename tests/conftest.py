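import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from flavatrial import COSMOS_THRESHOLDS, CohortParams, generate_cohort, table1_fixture


@pytest.fixture(scope="session")
def thresholds():
    return COSMOS_THRESHOLDS


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic cohort reproducing the published classification margins."""
    return table1_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic trial shared by tests that only need plausible data."""
    params = CohortParams(n_total=4000, seed=11)
    participants, samples, reports, events, _ = generate_cohort(params)
    return params, participants, samples, reports, events
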