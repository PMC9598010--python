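import random

import pytest

from molgrade.fixtures import (
    build_dehydration_products,
    build_glucose_forms,
    build_nitrosyl_fluoride,
)
from molgrade.structures import Atom, Bond, BondOrder, Molecule

_ELEMENTS = ["C", "N", "O", "F", "S", "H"]
_ORDERS = [BondOrder.SINGLE, BondOrder.SINGLE, BondOrder.DOUBLE, BondOrder.TRIPLE]


def random_molecule(rng: random.Random, max_atoms: int = 12) -> Molecule:
    """A random small labeled graph (not necessarily chemically sensible).

    Connected by construction (random spanning tree) plus a few extra edges;
    random charges, lone pairs and radicals exercise the coloring grammar.
    """
    n = rng.randint(1, max_atoms)
    atoms = [
        Atom(
            rng.choice(_ELEMENTS),
            formal_charge=rng.choice([0, 0, 0, 1, -1]),
            lone_pairs=rng.choice([0, 0, 1, 2, 3]),
            radical_electrons=rng.choice([0, 0, 0, 1]),
        )
        for _ in range(n)
    ]
    bonds = []
    seen = set()
    for i in range(1, n):
        j = rng.randrange(i)
        bonds.append(Bond(j, i, rng.choice(_ORDERS)))
        seen.add((j, i))
    extra = rng.randint(0, n // 2)
    for _ in range(extra):
        i, j = rng.randrange(n), rng.randrange(n)
        key = (min(i, j), max(i, j))
        if i != j and key not in seen:
            seen.add(key)
            bonds.append(Bond(key[0], key[1], rng.choice(_ORDERS)))
    return Molecule(atoms=atoms, bonds=bonds, name="random")


@pytest.fixture(scope="session")
def nof_pair():
    return build_nitrosyl_fluoride(True), build_nitrosyl_fluoride(False)


@pytest.fixture(scope="session")
def butenes():
    return build_dehydration_products()


@pytest.fixture(scope="session")
def glucose():
    return build_glucose_forms()
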