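import numpy as np
import pytest

from ehirt.estimation import make_grid_points, normal_grid
from ehirt.simulate import (
    AbilitySpec,
    default_item_bank,
    generate_responses,
    sample_abilities,
)


@pytest.fixture(scope="session")
def bank():
    return default_item_bank()


@pytest.fixture(scope="session")
def grid_points():
    return make_grid_points()


@pytest.fixture(scope="session")
def normal_weights():
    return normal_grid().weights


@pytest.fixture(scope="session")
def small_responses(bank):
    """A modest simulated dataset (n=400, normal abilities) for fast fits."""
    abilities = sample_abilities(400, AbilitySpec("normal"), 101)
    x = generate_responses(bank, abilities, 102).x.astype(float)
    return x, abilities
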