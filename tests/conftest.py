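import numpy as np
import pytest

from cytoswap.config import GrowthParams, ImageParams, MorphdbParams, SimulationConfig


@pytest.fixture
def ideal_config():
    """Perfect transmission and viability: deterministic genetics."""
    return SimulationConfig(seed=0, n_tetrads=10, plasmid_retention=1.0,
                            spore_viability=1.0)


@pytest.fixture
def noiseless_image_config():
    return SimulationConfig(
        seed=0, image_params=ImageParams(n_cells=25, noise_sd=0.0)
    )


@pytest.fixture
def small_morphdb_config():
    """Reduced strain count for fast unit tests (full scale is exercised in
    the acceptance suite)."""
    return SimulationConfig(
        seed=0, morphdb_params=MorphdbParams(n_strains=500, n_interactors=10)
    )
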