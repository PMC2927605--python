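import numpy as np
import pandas as pd
import pytest

from cohortdrift.cohort_simulator import AttritionModelSpec
from cohortdrift.io import (
    baseline_specs_from_config,
    load_baseline_config,
    load_table1_marginals,
    load_table2_coefficients,
)
from cohortdrift.pipeline import calibrated_model


@pytest.fixture(scope="session")
def baseline_config():
    return load_baseline_config()


@pytest.fixture(scope="session")
def specs(baseline_config):
    return baseline_specs_from_config(baseline_config)


@pytest.fixture(scope="session")
def spec_by_name(specs):
    return {s.name: s for s in specs}


@pytest.fixture(scope="session")
def table1():
    return load_table1_marginals()


@pytest.fixture(scope="session")
def table2():
    return load_table2_coefficients()


@pytest.fixture(scope="session")
def fixture_model(specs, baseline_config):
    """Coefficient fixture with intercepts calibrated to the Survey-5 targets."""
    return calibrated_model(specs, baseline_config)


@pytest.fixture(scope="session")
def null_model(specs, baseline_config):
    """All log odds ratios zero, intercepts calibrated to the same targets."""
    return calibrated_model(specs, baseline_config, null=True)


def two_bucket_update(p, retain_exposed, retain_unexposed):
    """Independent survivor-count oracle: exposed and unexposed masses are
    thinned by their retention probabilities and the prevalence renormalized."""
    e = p * retain_exposed
    u = (1.0 - p) * retain_unexposed
    return e / (e + u)
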