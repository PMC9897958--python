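import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from nhpi.grid import Raster
from nhpi.synthetic import LandscapeConfig, generate_landscape


@pytest.fixture(scope="session")
def small_landscape() -> Raster:
    """A 120x120-cell patch-mosaic landscape shared across tests."""
    return generate_landscape(
        LandscapeConfig(extent_cells=120, clumping=0.4, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
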