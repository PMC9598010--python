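"""Fragment enumeration: hand-derived counts, oracle agreement, invariants."""

import random
from collections import Counter

import pytest

from conftest import random_molecule
from molgrade.errors import UnsupportedSizeError
from molgrade.fragmenter import (
    BOND_SYMBOL,
    LP_LABEL,
    FragmentationScheme,
    atom_label,
    brute_force_paths,
    enumerate_fragments,
)
from molgrade.fixtures import build_nitrosyl_fluoride
from molgrade.structures import Atom, Bond, BondOrder, Molecule

DECORATED = FragmentationScheme(lone_pairs_as_pseudo_atoms=False)


def chain(*elements, orders=None):
    orders = orders or [BondOrder.SINGLE] * (len(elements) - 1)
    return Molecule(
        atoms=[Atom(e) for e in elements],
        bonds=[Bond(i, i + 1, o) for i, o in enumerate(orders)],
    )


def labels_from_index_paths(mol, index_paths, scheme):
    """Render the oracle's index paths with the fragment grammar."""
    esym = {}
    for b in mol.bonds:
        esym[(b.begin, b.end)] = esym[(b.end, b.begin)] = BOND_SYMBOL[b.order]
    labs = [atom_label(a, scheme) for a in mol.atoms]

    def render(path):
        parts = [labs[path[0]]]
        for u, v in zip(path, path[1:]):
            parts.append(esym[(u, v)])
            parts.append(labs[v])
        return "".join(parts)

    out = Counter()
    for path, count in index_paths.items():
        out[min(render(path), render(path[::-1]))] += count
    return out


class TestAtomLabel:
    def test_bare_neutral_carbon(self):
        assert atom_label(Atom("C"), FragmentationScheme()) == "C"

    def test_charge_suffix(self):
        assert atom_label(Atom("O", formal_charge=-1), FragmentationScheme()) == "O-1"
        assert atom_label(Atom("N", formal_charge=1), FragmentationScheme()) == "N+1"

    def test_lone_pair_counts_distinguish_labels(self):
        # a fluorine missing one lone pair must be a different feature
        f3 = atom_label(Atom("F", lone_pairs=3), DECORATED)
        f2 = atom_label(Atom("F", lone_pairs=2), DECORATED)
        assert f3 != f2

    def test_toggled_off_attributes_omitted(self):
        scheme = FragmentationScheme(use_formal_charge=False, use_radicals=False)
        a = Atom("N", formal_charge=1, radical_electrons=1)
        assert atom_label(a, scheme) == "N"


class TestEnumerateFragments:
    def test_single_atom_gives_atom_count_only(self):
        vec = enumerate_fragments(Molecule(atoms=[Atom("C")]))
        assert vec == Counter({"C": 1})

    def test_ethane_one_undirected_path(self):
        vec = enumerate_fragments(chain("C", "C"))
        assert vec == Counter({"C": 2, "C-C": 1})

    def test_propane_counts(self):
        vec = enumerate_fragments(chain("C", "C", "C"))
        assert vec == Counter({"C": 3, "C-C": 2, "C-C-C": 1})

    def test_bond_order_symbols(self):
        vec = enumerate_fragments(
            chain("C", "C", orders=[BondOrder.TRIPLE]),
            FragmentationScheme(include_atom_counts=False),
        )
        assert vec == Counter({"C#C": 1})

    def test_nitrosyl_fluoride_pseudo_atom_vectors(self):
        # Full hand enumeration of the default (pseudo-atom) descriptor
        # space for F-N=O with 3/1/2 lone pairs and the one-missing variant.
        complete = enumerate_fragments(build_nitrosyl_fluoride(True))
        expected = Counter({
            "F": 1, "N": 1, "O": 1, LP_LABEL: 6,
            "F-N": 1, "N=O": 1, "F-LP": 3, "LP-N": 1, "LP-O": 2,
            "LP-F-N": 3, "LP-F-LP": 3, "F-N=O": 1, "F-N-LP": 1,
            "LP-N=O": 1, "LP-O=N": 2, "LP-O-LP": 1,
            "LP-F-N=O": 3, "LP-F-N-LP": 3, "F-N=O-LP": 2, "LP-N=O-LP": 2,
        })
        assert complete == expected
        incomplete = enumerate_fragments(build_nitrosyl_fluoride(False))
        assert sum(incomplete.values()) == 32
        assert sum(complete.values()) == 39

    def test_permutation_invariance(self):
        rng = random.Random(11)
        for _ in range(20):
            mol = random_molecule(rng, max_atoms=8)
            perm = list(range(len(mol.atoms)))
            rng.shuffle(perm)
            inv = {old: new for new, old in enumerate(perm)}
            shuffled = Molecule(
                atoms=[mol.atoms[i] for i in perm],
                bonds=[Bond(inv[b.begin], inv[b.end], b.order) for b in mol.bonds],
            )
            assert enumerate_fragments(mol) == enumerate_fragments(shuffled)

    def test_isolated_atom_changes_only_atom_counts(self):
        mol = chain("C", "C", "C")
        grown = Molecule(atoms=mol.atoms + [Atom("N")], bonds=mol.bonds)
        a, b = enumerate_fragments(mol), enumerate_fragments(grown)
        assert b["N"] == a["N"] + 1
        assert {k: v for k, v in a.items() if "-" in k} == {
            k: v for k, v in b.items() if "-" in k
        }

    def test_toggle_off_conserves_count_mass(self):
        rng = random.Random(5)
        off = FragmentationScheme(
            use_formal_charge=False,
            use_radicals=False,
            use_lone_pairs=False,
        )
        for _ in range(10):
            mol = random_molecule(rng, max_atoms=8)
            # mass excluding lone-pair pseudo-atom contributions on the
            # default side: compare against the decoration scheme instead,
            # whose graph is identical to the uncolored one.
            a = enumerate_fragments(mol, DECORATED)
            b = enumerate_fragments(mol, off)
            assert sum(a.values()) == sum(b.values())
            assert len(b) <= len(a)

    def test_pseudo_atom_mode_equals_explicit_expansion(self):
        # Expanding each lone pair into an explicit helium leaf reproduces
        # the pseudo-atom graph up to the label string (He never collides
        # with the generator's element set in canonical ordering).
        rng = random.Random(23)
        for _ in range(10):
            mol = random_molecule(rng, max_atoms=6)
            atoms = [
                Atom(a.element, a.formal_charge, a.radical_electrons)
                for a in mol.atoms
            ]
            bonds = list(mol.bonds)
            for i, a in enumerate(mol.atoms):
                for _ in range(a.lone_pairs):
                    atoms.append(Atom("He"))
                    bonds.append(Bond(i, len(atoms) - 1))
            expanded = Molecule(atoms=atoms, bonds=bonds)
            got = enumerate_fragments(mol)
            via_he = Counter(
                {
                    k.replace("He", LP_LABEL): v
                    for k, v in enumerate_fragments(expanded).items()
                }
            )
            assert got == via_he


class TestBruteForceOracle:
    def test_cyclopropane_paths(self):
        k3 = Molecule(
            atoms=[Atom("C")] * 3,
            bonds=[Bond(0, 1), Bond(1, 2), Bond(0, 2)],
        )
        paths = brute_force_paths(k3, 2, 3)
        assert sum(v for k, v in paths.items() if len(k) == 2) == 3
        assert sum(v for k, v in paths.items() if len(k) == 3) == 3

    def test_path_graph_combinatorics(self):
        p4 = chain("C", "C", "C", "C")
        paths = brute_force_paths(p4, 2, 4)
        assert sum(paths.values()) == 3 + 2 + 1

    def test_star_graph(self):
        s3 = Molecule(
            atoms=[Atom("C")] * 4,
            bonds=[Bond(0, 1), Bond(0, 2), Bond(0, 3)],
        )
        paths = brute_force_paths(s3, 2, 3)
        assert sum(v for k, v in paths.items() if len(k) == 2) == 3
        assert sum(v for k, v in paths.items() if len(k) == 3) == 3

    def test_size_guard(self):
        big = Molecule(atoms=[Atom("C") for _ in range(13)])
        with pytest.raises(UnsupportedSizeError):
            brute_force_paths(big)

    def test_enumeration_agrees_with_oracle_on_random_graphs(self):
        rng = random.Random(42)
        scheme = FragmentationScheme(
            include_atom_counts=False, lone_pairs_as_pseudo_atoms=False
        )
        for _ in range(50):
            mol = random_molecule(rng)
            expected = labels_from_index_paths(
                mol, brute_force_paths(mol, 2, 4), scheme
            )
            assert enumerate_fragments(mol, scheme) == expected
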