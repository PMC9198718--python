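import numpy as np
import pytest

from clc4pipe import CellPassiveSpec, ProtocolSpec, get_variant, simulate_cell


@pytest.fixture(scope="session")
def protocol():
    return ProtocolSpec()


@pytest.fixture(scope="session")
def quiet_passive():
    """Noise-free passive cell: the simulator becomes a closed-form object."""
    return CellPassiveSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_passive():
    return CellPassiveSpec()


@pytest.fixture(scope="session")
def wt():
    return get_variant("WT")


@pytest.fixture(scope="session")
def quiet_wt_recording(wt, protocol, quiet_passive):
    """One noise-free WT cell, reused across read-only tests."""
    return simulate_cell(wt, protocol, quiet_passive, seed=7)


@pytest.fixture(scope="session")
def noisy_wt_recording(wt, protocol, noisy_passive):
    return simulate_cell(wt, protocol, noisy_passive, seed=7)
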