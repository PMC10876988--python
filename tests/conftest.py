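import numpy as np
import pytest

from ramanprep.decompose import build_component_pools
from ramanprep.io import Spectrum, WavenumberAxis
from ramanprep.synthesis import SynthesisConfig, generate_mathsim_sources


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def axis_1024():
    return WavenumberAxis(np.linspace(400.0, 1800.0, 1024))


@pytest.fixture
def small_cfg():
    """A 256-point synthesis config for fast tests."""
    return SynthesisConfig(n_spectra=10, grid_len=256, seed=7)


@pytest.fixture
def small_pools(small_cfg, rng):
    sources = generate_mathsim_sources(12, small_cfg, rng)
    return build_component_pools(sources)


@pytest.fixture
def ramp_spectrum():
    ax = np.linspace(400.0, 1800.0, 64)
    return Spectrum(WavenumberAxis(ax), np.linspace(1.0, 5.0, 64))
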