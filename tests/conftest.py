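import numpy as np
import pytest

from centiclock import clocks, preprocess
from centiclock.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default-scale synthetic cohort (600 samples x 2000 CpGs)."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for fast unit tests."""
    return simulate_cohort(SimConfig(n_samples=200, n_cpgs=400, seed=7))


@pytest.fixture(scope="session")
def prefiltered(default_cohort):
    """Age-informative CpG subset of the default cohort plus its sheet."""
    beta, sheet, _, _ = default_cohort
    pre = preprocess.prefilter_cpgs(beta, sheet["age"], n_pos=150, n_neg=150,
                                    eps_null=0.05, n_null=100)
    return beta.loc[pre.selected], sheet


@pytest.fixture(scope="session")
def fitted_weighted_clock(prefiltered):
    """Centenarian-weighted elastic-net clock fitted on the default cohort."""
    sub, sheet = prefiltered
    ages = sheet["age"].to_numpy(dtype=float)
    w = clocks.sample_weights(ages, 10.0)
    model = clocks.ElasticNetClock(sub, ages, weights=w, seed=0)
    return model.fit(lambda_="cv", cv_folds=5)
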