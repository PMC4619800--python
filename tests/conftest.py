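import numpy as np
import pytest

from ontodyn.io_tables import AgeDesign, ExpressionMatrix
from ontodyn.synthetic_data import load_archetypes, simulate_expression


@pytest.fixture(scope="session")
def design():
    return AgeDesign.default()


@pytest.fixture(scope="session")
def archetypes():
    return load_archetypes()


@pytest.fixture(scope="session")
def six_archetype_matrix(design):
    """600 genes, uniform over the six archetypes, moderate noise."""
    mix = {label: 1 / 6 for label in load_archetypes().group_labels}
    matrix, truth = simulate_expression(600, mix=mix, noise_sd=0.3,
                                        design=design, seed=11)
    return matrix, truth


def random_matrix(n_features, design, seed=0, level="gene"):
    rng = np.random.default_rng(seed)
    ids = [f"f{i}" for i in range(n_features)]
    values = np.exp2(rng.normal(5, 2, (n_features, design.n_samples)))
    return ExpressionMatrix(ids, values, design, level)


@pytest.fixture
def small_matrix(design):
    return random_matrix(8, design, seed=3)
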