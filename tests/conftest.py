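import numpy as np
import pytest

from pepccs import (
    Atom,
    Geometry,
    build_polyglycine,
    get_buffer_gas,
    make_toy_ion,
)


@pytest.fixture(scope="session")
def n2():
    return get_buffer_gas("N2")


@pytest.fixture(scope="session")
def helium():
    return get_buffer_gas("He")


@pytest.fixture(scope="session")
def gly6():
    """Protonated hexaglycine, 46 atoms — the standard small-peptide fixture."""
    return build_polyglycine(6, "helical", protonated=True)


@pytest.fixture(scope="session")
def single_carbon():
    return make_toy_ion("single_atom", element="C")


@pytest.fixture
def random_charged_cloud():
    """Asymmetric 5-atom charged fixture for potential/gradient checks."""
    rng = np.random.default_rng(42)
    elements = ["C", "N", "O", "C", "H"]
    charges = [0.3, -0.2, 0.1, 0.5, 0.3]
    pos = rng.normal(scale=2.0, size=(5, 3))
    return Geometry(
        [Atom(e, p, q) for e, p, q in zip(elements, pos, charges)],
        label="cloud5",
    )
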