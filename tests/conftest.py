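import numpy as np
import pytest

from shellsim.similarity import LayerScheme
from shellsim.structure_io import structure_from_arrays
from shellsim.synthetic_data import StructureSpec, make_structure, table1_weights


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def weights():
    return table1_weights()


@pytest.fixture
def default_structure():
    """A medium synthetic structure with the default radial profile."""
    st, truth = make_structure(StructureSpec(n_atoms=600, seed=11))
    return st, truth


@pytest.fixture
def two_shell_scheme():
    return LayerScheme((10.0,))


def make_simple(coords, elements=None, **kw):
    """Tiny structure from raw coordinates (helper, not a fixture)."""
    coords = np.asarray(coords, dtype=float)
    if elements is None:
        elements = ["C"] * len(coords)
    return structure_from_arrays("toy", coords, elements, **kw)
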