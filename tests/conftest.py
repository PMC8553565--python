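import pytest

from csdsim import SCENARIOS, simulate


@pytest.fixture(scope="session")
def fig5b_trace():
    """Physiological persistent fraction (1 %), gD_i = 0.1, 30 s."""
    return simulate(SCENARIOS["fig5b"])


@pytest.fixture(scope="session")
def fig5c_trace():
    """Pathological persistent fraction (6 %), gD_i = 0.1, 30 s."""
    return simulate(SCENARIOS["fig5c"])
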