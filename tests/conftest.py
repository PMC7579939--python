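import numpy as np
import pytest

from axialgrowth import (
    default_cohort_spec,
    generate_cohort,
    reference_linear_model,
)

#: Covariates at which curves/derivatives are evaluated in several tests.
CURVE_COVARIATES = {"sex": 1.0, "ser": -3.0, "k_mean": 43.0, "cct": 550.0, "wtw": 12.0}


@pytest.fixture(scope="session")
def reference_model():
    return reference_linear_model()


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """300 eyes generated exactly on the reference regression surface."""
    spec = default_cohort_spec(n=300, seed=7).with_(residual_sd=0.0)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort under the default (published-marginals) conditions."""
    return generate_cohort(default_cohort_spec(n=1011, seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(default_cohort_spec(n=250, seed=21))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
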