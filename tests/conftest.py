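import warnings

import pytest

from droughtvigor.cohort import run_report
from droughtvigor.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across the suite."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def default_report(default_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_report(default_cohort)
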