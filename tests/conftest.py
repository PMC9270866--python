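import numpy as np
import pytest

from rvk import averaged_beat
from rvk.phantom import PhantomConfig, generate_phantom
from rvk.recording import CrystalLayout


@pytest.fixture(scope="session")
def layout():
    return CrystalLayout.default()


@pytest.fixture(scope="session")
def nf_config():
    """Noise-free phantom at the default study conditions."""
    return PhantomConfig(noise_sd=0.0, seed=101)


@pytest.fixture(scope="session")
def nf_pair(nf_config):
    """(baseline, tra, truth) for the noise-free phantom."""
    return generate_phantom(nf_config)


@pytest.fixture(scope="session")
def nf_beats(nf_pair):
    """Averaged beats (baseline, tra) of the noise-free phantom."""
    base, tra, _ = nf_pair
    return averaged_beat(base), averaged_beat(tra)


@pytest.fixture(scope="session")
def noisy_pair():
    cfg = PhantomConfig(noise_sd=0.1, seed=202)
    return generate_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
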