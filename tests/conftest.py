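import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cicquant.synthetic_data import SceneSpec, generate_coincubation_scene


@pytest.fixture(scope="session")
def clean_scene():
    """One zero-noise scene with known composition, shared across tests."""
    spec = SceneSpec(n_viable_free=5, n_dead_free=3, n_cic=2, noise_sigma=0.0, seed=7)
    stack, truth = generate_coincubation_scene(spec)
    return spec, stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
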