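import numpy as np
import pytest

from frogbic import ExpressionMatrix, PlantedBicluster, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """The 2×2 worked example D = [[1, 2], [3, 5]]."""
    return ExpressionMatrix(
        np.array([[1.0, 2.0], [3.0, 5.0]]), ("g1", "g2"), ("c1", "c2")
    )


@pytest.fixture
def small_planted():
    """A 60×12 matrix with one noise-free additive 12×5 plant."""
    plant = PlantedBicluster(tuple(range(12)), tuple(range(5)),
                             pattern="additive", noise_sd=0.0)
    matrix, plants = generate_synthetic(60, 12, ("normal", 0.0, 1.0), [plant], seed=7)
    return matrix, plants[0]


def write_tsv(path, text):
    path.write_text(text)
    return path
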