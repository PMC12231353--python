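import numpy as np
import pytest

from screwscape.design import TRAINING_GRID, lhs_design
from screwscape.geometry import default_geometry
from screwscape.oracle import default_params, generate_dataset


@pytest.fixture(scope="session")
def geom():
    return default_geometry()


@pytest.fixture(scope="session")
def params():
    return default_params(seed=0)


@pytest.fixture(scope="session")
def small_dataset(geom, params):
    """200-row labelled oracle dataset on the training grid."""
    design = lhs_design(200, TRAINING_GRID, seed=42)
    return generate_dataset(design, geom, params)
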