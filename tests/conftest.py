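import numpy as np
import pytest

from hostguest.structures import (
    Atom,
    Molecule,
    default_fragment_system,
    read_structure,
    sevoflurane_path,
)


@pytest.fixture(scope="session")
def fragment_system():
    return default_fragment_system()


@pytest.fixture(scope="session")
def sevoflurane():
    return read_structure(sevoflurane_path(), format="sdf")


@pytest.fixture
def single_carbon():
    return Molecule("C1", [Atom("C", np.zeros(3), 1.7, "C")])


def random_molecule(rng: np.random.Generator, n_atoms: int) -> Molecule:
    """Random heavy-atom blob with constants from the packaged table."""
    elements = rng.choice(["C", "N", "O", "F", "S"], size=n_atoms)
    coords = rng.normal(scale=4.0, size=(n_atoms, 3))
    atoms = [Atom(el, xyz, 1.6, el) for el, xyz in zip(elements, coords)]
    return Molecule("random", atoms)
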