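import numpy as np
import numpy.linalg as la
import pytest

from popcoupling.data_io import apply_exclusions
from popcoupling.kinematics import compute_aspects, mean_body_speed, preprocess_positions
from popcoupling.synth import SynthParams, generate_session


@pytest.fixture(scope="session")
def default_session():
    """A 30-unit, 30-min synthetic session at generator defaults."""
    return generate_session(SynthParams(n_units=30), seed=0)


@pytest.fixture(scope="session")
def retained_spikes(default_session):
    session, _ = default_session
    result = apply_exclusions(session)
    assert not result.excluded
    return result.session.spikes


@pytest.fixture(scope="session")
def session_speed(default_session):
    session, _ = default_session
    _, vel = preprocess_positions(session.beads)
    return mean_body_speed(la.norm(vel, axis=2))


@pytest.fixture(scope="session")
def session_kinematics(default_session):
    session, _ = default_session
    return compute_aspects(session.beads)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
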