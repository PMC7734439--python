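import numpy as np
import pytest

from blindbet import observer, synth
from blindbet.pipeline import FIT_SIGMA_GRID


@pytest.fixture(scope="session")
def config():
    return observer.ObserverConfig(seed=11)


@pytest.fixture(scope="session")
def prediction(config):
    """One shared Monte Carlo prediction table (full e grid x fit sigma grid)."""
    return observer.predict_psychometric(config, sigma_grid=FIT_SIGMA_GRID)


@pytest.fixture(scope="session")
def session_spec():
    return synth.SessionSpec()


@pytest.fixture(scope="session")
def cohort_records(session_spec, config):
    """One noiseless 29-subject cohort's behavioral records."""
    subjects = synth.default_cohort(29, sigma_type2=0.0, seed=21)
    return synth.simulate_cohort(subjects, session_spec, config, seed=22)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
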