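import numpy as np
import pytest

from helixafm import GeneratorConfig, build_filament_model, default_states


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def zero_var_config():
    """All structural SDs zero: every draw hits the state means exactly."""
    states = default_states()
    for sp in states.values():
        sp.pitch_sd_struct_nm = 0.0
        sp.peak_height_sd_nm = 0.0
    return GeneratorConfig(
        states=states, noise_sd_nm=0.0, localization_jitter_nm=0.0
    )


@pytest.fixture
def default_config():
    return GeneratorConfig()


@pytest.fixture
def bare_model(zero_var_config, rng):
    return build_filament_model(zero_var_config, 6, rng=rng)
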