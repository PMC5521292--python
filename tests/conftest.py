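import numpy as np
import pytest
from hypothesis import settings

import polychannel as pc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def smooth_spec():
    """Narrow smooth channel used for fast MD tests."""
    return pc.ChannelSpec(mean_radius=4.0, amplitude=0.0, harmonic=0, box_length=28.555)


@pytest.fixture(scope="session")
def wavy_spec():
    return pc.ChannelSpec(
        mean_radius=6.0, amplitude=1.5, harmonic=1, box_length=57.11, wavelength=57.11
    )


@pytest.fixture(scope="session")
def small_system(smooth_spec):
    """Small built system (chain + ions + solvent + walls), session-cached."""
    cfg = pc.BuildConfig(spec=smooth_spec, chain_length=10, seed=42)
    return pc.build_system(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
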