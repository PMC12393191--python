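import numpy as np
import pytest

from esmgre import (
    build_figure2_phantom,
    design_sequence,
    get_preset,
)


@pytest.fixture(scope="session")
def table1_config():
    return get_preset("table1_invivo")


@pytest.fixture(scope="session")
def table1_design(table1_config):
    """Echo train and waveform of the in vivo 64-echo/K=10 protocol."""
    return design_sequence(table1_config)


@pytest.fixture(scope="session")
def sim_config():
    return get_preset("sim_64x64_k10")


@pytest.fixture(scope="session")
def sim_design(sim_config):
    """Train and waveform of the desk-scale 64x64 simulation protocol."""
    return design_sequence(sim_config)


@pytest.fixture(scope="session")
def sim_phantom(sim_config):
    return build_figure2_phantom(sim_config)


def nrmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))
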