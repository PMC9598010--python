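"""Programmatic worked-example structures.

Everything the tests and examples grade is built here, in code — nothing is
downloaded. Three question sets are covered:

* a Lewis-structure question (nitrosyl fluoride, F–N=O, with full lone-pair
  bookkeeping and an "incomplete" student variant missing one fluorine lone
  pair);
* a regioselectivity question (major vs. minor dehydration product of
  2,3-dimethyl-2-butanol: 2,3-dimethyl-2-butene vs. 2,3-dimethyl-1-butene);
* a stereochemistry question: the 8 accepted drawings of D-glucose (two
  open-chain forms with and without an explicit aldehyde hydrogen, and
  α-/β-/undefined anomers of the furanose and pyranose rings) plus a student
  open-chain drawing with exactly one tetrahedral center inverted.

Stereo-bearing fixtures are built from verified isomeric SMILES: 2D
coordinates and wedge assignments are produced by RDKit's depiction code, so
the InChI generator perceives exactly the intended configurations. The
glucose tests assert the expected ``/t`` layer contents rather than trusting
the drawing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .structures import (
    Atom,
    Bond,
    BondOrder,
    Molecule,
    read_molfile,
    write_sdf,
)

__all__ = [
    "FixtureSet",
    "build_nitrosyl_fluoride",
    "build_dehydration_products",
    "build_glucose_forms",
    "build_glucose_student",
    "molecule_from_smiles",
    "all_fixture_molecules",
    "write_fixture_sdfs",
    "GLUCOSE_SMILES",
]

# Isomeric SMILES of the glucose forms. The open-chain string carries the
# InChIKey of aldehydo-D-glucose (GZCGUPFRVQAUEE-SLPGGIOYSA-N); the pyranose
# anomers match the α-/β-D-glucopyranose keys (WQZGKKKJIJFFOK-DVKNGEFBSA-N /
# -VFUOTHLCSA-N). Cyclic forms are the open chain re-wired through the ring
# oxygen with every SMILES neighbor ordering preserved, so the open-chain
# configurations carry over unchanged.
GLUCOSE_SMILES = {
    "open": "OC[C@@H](O)[C@@H](O)[C@H](O)[C@@H](O)C=O",
    "furanose_alpha": "OC[C@@H](O)[C@@H](O1)[C@H](O)[C@@H](O)[C@H]1O",
    "furanose_beta": "OC[C@@H](O)[C@@H](O1)[C@H](O)[C@@H](O)[C@@H]1O",
    "furanose_undefined": "OC[C@@H](O)[C@@H](O1)[C@H](O)[C@@H](O)C1O",
    "pyranose_alpha": "OC[C@@H](O1)[C@@H](O)[C@H](O)[C@@H](O)[C@H]1O",
    "pyranose_beta": "OC[C@@H](O1)[C@@H](O)[C@H](O)[C@@H](O)[C@@H]1O",
    "pyranose_undefined": "OC[C@@H](O1)[C@@H](O)[C@H](O)[C@@H](O)C1O",
}

# Open-chain student drawings with exactly one inverted tetrahedral center,
# keyed by sugar carbon number (C2 is adjacent to the aldehyde). The stereo
# atoms appear in the SMILES in the order C5, C4, C3, C2.
_OPEN_INVERTED = {
    5: "OC[C@H](O)[C@@H](O)[C@H](O)[C@@H](O)C=O",
    4: "OC[C@@H](O)[C@H](O)[C@H](O)[C@@H](O)C=O",
    3: "OC[C@@H](O)[C@@H](O)[C@@H](O)[C@@H](O)C=O",
    2: "OC[C@@H](O)[C@@H](O)[C@H](O)[C@H](O)C=O",
}


@dataclass
class FixtureSet:
    """A named collection of molecules plus expected outcomes for tests."""

    name: str
    molecules: dict[str, Molecule]
    teacher_names: list[str] = field(default_factory=list)
    student_name: str | None = None
    expected: dict = field(default_factory=dict)

    @property
    def teachers(self) -> list[Molecule]:
        return [self.molecules[n] for n in self.teacher_names]

    @property
    def student(self) -> Molecule:
        if self.student_name is None:
            raise KeyError(f"fixture set {self.name!r} has no student structure")
        return self.molecules[self.student_name]


def molecule_from_smiles(
    smiles: str, name: str = "", explicit_h_on_carbonyl: bool = False
) -> Molecule:
    """Build a Molecule from SMILES with 2D coordinates and wedge flags.

    RDKit computes the depiction and wedges the stereocenters; the MOL block
    is then read back through this package's own reader so the result is a
    plain :class:`Molecule` like any other input.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ValueError(f"bad fixture SMILES: {smiles!r}")
    if explicit_h_on_carbonyl:
        carbonyl = [
            a.GetIdx()
            for a in rd.GetAtoms()
            if a.GetSymbol() == "C"
            and a.GetTotalNumHs() == 1
            and any(
                b.GetBondType() == Chem.BondType.DOUBLE
                and b.GetOtherAtom(a).GetSymbol() == "O"
                for b in a.GetBonds()
            )
        ]
        if not carbonyl:
            raise ValueError("no carbonyl CH found to add an explicit hydrogen to")
        rd = Chem.AddHs(rd, onlyOnAtoms=carbonyl)
    AllChem.Compute2DCoords(rd)
    mol = read_molfile(Chem.MolToMolBlock(rd, kekulize=True))
    mol.name = name
    return mol


def build_nitrosyl_fluoride(complete: bool = True) -> Molecule:
    """Lewis structure of nitrosyl fluoride, F–N=O.

    The complete drawing carries the full octet bookkeeping: 3 lone pairs on
    F, 1 on N, 2 on O (6 in total). The incomplete student variant forgets
    exactly one lone pair on the fluorine; bonds are identical.
    """
    return Molecule(
        atoms=[
            Atom("F", lone_pairs=3 if complete else 2, x=-1.0),
            Atom("N", lone_pairs=1, x=0.0),
            Atom("O", lone_pairs=2, x=1.0),
        ],
        bonds=[
            Bond(0, 1, BondOrder.SINGLE),
            Bond(1, 2, BondOrder.DOUBLE),
        ],
        name="nitrosyl fluoride" + ("" if complete else " (one F lone pair missing)"),
    )


def build_dehydration_products() -> tuple[Molecule, Molecule]:
    """Major and minor dehydration products of 2,3-dimethyl-2-butanol.

    Returns ``(major, minor)``: the Zaitsev product 2,3-dimethyl-2-butene
    (tetrasubstituted alkene) and 2,3-dimethyl-1-butene. Both C6H12, drawn
    without explicit hydrogens.
    """
    major = molecule_from_smiles("CC(C)=C(C)C", "2,3-dimethyl-2-butene")
    minor = molecule_from_smiles("C=C(C)C(C)C", "2,3-dimethyl-1-butene")
    return major, minor


def build_glucose_student(inverted_center: int = 2) -> Molecule:
    """Open-chain glucose drawing with one inverted center and explicit CHO-H.

    ``inverted_center`` picks which sugar carbon (2–5) disagrees with
    D-glucose; the stereo fraction 3/4 is invariant to the choice.
    """
    if inverted_center not in _OPEN_INVERTED:
        raise ValueError(f"inverted_center must be one of 2..5, got {inverted_center}")
    return molecule_from_smiles(
        _OPEN_INVERTED[inverted_center],
        f"student glucose (C{inverted_center} inverted, explicit aldehyde H)",
        explicit_h_on_carbonyl=True,
    )


def build_glucose_forms(student_inverted_center: int = 2) -> FixtureSet:
    """The 8 accepted glucose drawings plus the erroneous student drawing."""
    molecules = {
        "open_implicit_h": molecule_from_smiles(
            GLUCOSE_SMILES["open"], "D-glucose, open chain"
        ),
        "open_explicit_h": molecule_from_smiles(
            GLUCOSE_SMILES["open"],
            "D-glucose, open chain, explicit aldehyde H",
            explicit_h_on_carbonyl=True,
        ),
        "furanose_alpha": molecule_from_smiles(
            GLUCOSE_SMILES["furanose_alpha"], "alpha-D-glucofuranose"
        ),
        "furanose_beta": molecule_from_smiles(
            GLUCOSE_SMILES["furanose_beta"], "beta-D-glucofuranose"
        ),
        "furanose_undefined": molecule_from_smiles(
            GLUCOSE_SMILES["furanose_undefined"],
            "D-glucofuranose, undefined anomer",
        ),
        "pyranose_alpha": molecule_from_smiles(
            GLUCOSE_SMILES["pyranose_alpha"], "alpha-D-glucopyranose"
        ),
        "pyranose_beta": molecule_from_smiles(
            GLUCOSE_SMILES["pyranose_beta"], "beta-D-glucopyranose"
        ),
        "pyranose_undefined": molecule_from_smiles(
            GLUCOSE_SMILES["pyranose_undefined"],
            "D-glucopyranose, undefined anomer",
        ),
        "student": build_glucose_student(student_inverted_center),
    }
    return FixtureSet(
        name="glucose",
        molecules=molecules,
        teacher_names=[
            "open_implicit_h",
            "open_explicit_h",
            "furanose_alpha",
            "furanose_beta",
            "furanose_undefined",
            "pyranose_alpha",
            "pyranose_beta",
            "pyranose_undefined",
        ],
        student_name="student",
        expected={"stereo_correct": 3, "stereo_total": 4, "g_rest": 0.75},
    )


def all_fixture_molecules() -> dict[str, Molecule]:
    """Every fixture molecule, for round-trip and validation sweeps."""
    out = {
        "nof_complete": build_nitrosyl_fluoride(True),
        "nof_incomplete": build_nitrosyl_fluoride(False),
    }
    major, minor = build_dehydration_products()
    out["butene_major"] = major
    out["butene_minor"] = minor
    glucose = build_glucose_forms()
    for key, mol in glucose.molecules.items():
        out[f"glucose_{key}"] = mol
    return out


def write_fixture_sdfs(outdir: str | Path) -> list[Path]:
    """Write all fixture sets as SDF files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    glucose = build_glucose_forms()
    files = {
        "nitrosyl_fluoride.sdf": [
            build_nitrosyl_fluoride(True),
            build_nitrosyl_fluoride(False),
        ],
        "dehydration_products.sdf": list(build_dehydration_products()),
        "glucose_teachers.sdf": glucose.teachers,
        "glucose_student.sdf": [glucose.student],
    }
    written = []
    for fname, mols in files.items():
        path = outdir / fname
        path.write_text(write_sdf(mols))
        written.append(path)
    return written
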