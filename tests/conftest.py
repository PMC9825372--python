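import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from primeseq.priming import run_study
from primeseq.simulate import make_fixture_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """One default-noise synthetic study shared across tests."""
    return make_fixture_study(101)


@pytest.fixture(scope="session")
def study_report(study):
    return run_study(study.genome, study.counts, study.tracks, study.igg)


@pytest.fixture(scope="session")
def noise_free_study():
    return make_fixture_study(7, noise_free=True)


@pytest.fixture(scope="session")
def noise_free_report(noise_free_study):
    st = noise_free_study
    return run_study(
        st.genome, st.counts, st.tracks, st.igg,
        peak_threshold="numeric", numeric_fraction=1.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
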