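import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phaseflow import (
    GrowthParams,
    SLGEConfig,
    compute_phase_boundaries,
    simulate_slge,
)
from phaseflow.classify import classify_donor
from phaseflow.synth import default_donor_spec, generate_donor

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    """The representative simulation parameterization (r=1.2, K=100, x0=1)."""
    return GrowthParams(r=1.2, K=100.0, x0=1.0)


@pytest.fixture(scope="session")
def boundaries(params):
    return compute_phase_boundaries(params)


@pytest.fixture(scope="session")
def ensemble(params):
    """Seeded 100-iteration sLGE ensemble at sigma = 0.1."""
    return simulate_slge(SLGEConfig(params=params, sigma=0.1, n_iter=100, seed=2024))


@pytest.fixture(scope="session")
def donor_data():
    """Default 12-taxon synthetic donor, 60 time points, frozen seed."""
    return generate_donor(default_donor_spec(seed=0))


@pytest.fixture(scope="session")
def donor_calls(donor_data):
    return classify_donor(donor_data.series)


def recovery_fraction(data, calls):
    """Fraction of non-midlog truth labels recovered by the classifier."""
    truth = dict(zip(data.truth.taxon, data.truth.true_phase))
    non_mid = [c for c in calls if truth[c.taxon] != "midlog"]
    hits = sum(1 for c in non_mid if c.phase == truth[c.taxon])
    return hits / len(non_mid)


@pytest.fixture(scope="session")
def recovery():
    return recovery_fraction
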