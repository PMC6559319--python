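import numpy as np
import pytest

from camopipe import load_background_style, load_mapping, load_receptor_set


@pytest.fixture(scope="session")
def fish_set():
    """Pollack dichromat: w = 0.05 for the most abundant class, LW 339 : SW 168."""
    return load_receptor_set("pollack_dichromat")


@pytest.fixture(scope="session")
def human_set():
    """Human trichromat with explicit per-receptor Weber fractions."""
    return load_receptor_set("human_trichromat")


@pytest.fixture(scope="session")
def fish_mapping():
    return load_mapping("pollack_mapping")


@pytest.fixture(scope="session")
def human_mapping():
    return load_mapping("human_mapping")


@pytest.fixture(scope="session")
def mudflat_style():
    return load_background_style("mudflat")


@pytest.fixture(scope="session")
def rockpool_style():
    return load_background_style("rockpool")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
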