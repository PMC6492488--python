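import numpy as np
import pytest

from s6lattice import UnitCell, cell_to_s6, generate_cells, random_reduced, selling_reduce, unreduce_random


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ortho_cell():
    """The worked-example orthorhombic cell."""
    return UnitCell(10, 12, 20, 90, 90, 90)


@pytest.fixture
def rhombo_cell():
    """60° rhombohedral cell whose S6 vector is unreduced (positive scalars)."""
    return UnitCell(1, 1, 1, 60, 60, 60)


def random_cells(n, rng, length_range=(3.0, 60.0)):
    """Random valid cells via the synthetic generator."""
    return generate_cells(n, mode="random", seed=rng, length_range=length_range).cells


def random_reduced_vectors(n, rng, scale=100.0):
    return random_reduced(n, rng, scale=scale)


def random_unreduced(n, rng, scale=100.0, max_steps=3):
    """Unreduced presentations of random lattices (same-lattice ground truth known)."""
    out = []
    for v in random_reduced(n, rng, scale=scale):
        out.append(unreduce_random(v, int(rng.integers(1, max_steps + 1)), rng))
    return np.stack(out)
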