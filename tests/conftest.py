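import numpy as np
import pytest

from strinet.behavior import extract_event_windows
from strinet.synthetic import SimConfig, gen_behavior_session


@pytest.fixture(scope="session")
def stage1_session():
    """One deterministic stage-1 behavior session shared across tests."""
    cfg = SimConfig(seed=7, session_duration=1200.0)
    session, manifest = gen_behavior_session(cfg, stage=1)
    return session, manifest


@pytest.fixture(scope="session")
def stage1_windows(stage1_session):
    session, _ = stage1_session
    return extract_event_windows(session)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
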