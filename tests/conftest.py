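import logging

import numpy as np
import pytest

from icterus.cohort import CohortConfig, simulate_cohort
from icterus.pipeline import RunConfig, run_experiment

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 57-case / 31-control cohort."""
    return simulate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def default_report():
    """Full default experiment (all four models, both pathways), run once.

    Shared across tests because cross-validating the set network dominates
    the suite's runtime.
    """
    return run_experiment(RunConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
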