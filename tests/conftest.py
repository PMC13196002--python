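import numpy as np
import pytest

from gaitsig.synthetic import EffectSpec, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_config():
    """One joint-plane, both sides — keeps generator tests fast."""
    return SimConfig(
        seed=7,
        joints=[("knee", "sagittal", "left"), ("knee", "sagittal", "right")],
        effect_specs=[],
    )


@pytest.fixture
def knee_effect_config(small_config):
    return small_config.with_(
        effect_specs=[EffectSpec("knee", "sagittal", 57, 76, -8.0)]
    )
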