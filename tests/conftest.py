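import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import eegdyn as ed


@pytest.fixture(scope="session")
def balanced_envelope():
    """300-s balanced lognormal envelope (H=0.75) at 250 Hz, for oracle tests."""
    return ed.generate_envelope(0.75, 75000, 250.0, seed=42)


@pytest.fixture(scope="session")
def scheduled_recording():
    """Recording with a scripted rest/sws/active schedule and clean signal."""
    spec = ed.SyntheticSpec(
        duration_s=250.0, fs=500.0,
        state_schedule=(("rest", 100.0), ("sws", 50.0), ("rest", 100.0)),
        seed=7,
    )
    return ed.generate_recording(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
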