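import numpy as np
import pytest

from condensatekit import synthdata


@pytest.fixture(scope="session")
def small_scene():
    """A modest two-channel scene with planted partition 3, co-enrichment 2."""
    image, truth = synthdata.gen_condensate_scene(
        n_nuclei=8, partition=3.0, cochannel_enrichment=2.0, snr=10.0, seed=42)
    return image, truth


@pytest.fixture(scope="session")
def fish_scene():
    image, truth = synthdata.gen_fish_scene(n_spots=30, seed=11)
    return image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
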