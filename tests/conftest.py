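import numpy as np
import pytest

from parasolsim.circuit_model import GanglionModelConfig
from parasolsim.stimuli import TextureSpec, generate_texture_sequence


@pytest.fixture(scope="session")
def texture_pair():
    """A small approaching texture and its exact time-reversal."""
    spec = TextureSpec.from_geometric_mean(1.6, 2.0, 1.0, seed=42)
    approach = generate_texture_sequence(spec, 64, 64, pixel_pitch=4.0)
    return approach, approach.time_reversed()


@pytest.fixture()
def quiet_config():
    """Nonlinear-variant model with noise disabled, for deterministic runs."""
    return GanglionModelConfig(variant="nonlinear", noise_scale=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
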