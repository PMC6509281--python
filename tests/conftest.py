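import numpy as np
import pytest

from slowstates.synth import SynthParams, generate_session


@pytest.fixture(scope="session")
def short_session():
    """120-s spontaneous session with LFP, spikes and ground truth."""
    return generate_session(SynthParams(), 120.0, seed=11)


@pytest.fixture(scope="session")
def uncoupled_session():
    """120-s session without VPM->PV coupling (independence null)."""
    return generate_session(SynthParams(coupling_gain=0.0), 120.0, seed=12,
                            with_lfp=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
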