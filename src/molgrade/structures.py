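"""Molecule data model and structure I/O.

The in-memory model is a plain labeled graph: atoms carry element, formal
charge, radical electrons and lone pairs; bonds carry an order and the stereo
wedge flag read from the source file. Unlike a cheminformatics toolkit mol
object, nothing is ever normalized behind the caller's back: no hydrogens are
added or removed, no valence model is applied, disconnected structures are
kept as drawn. Hydrogen management and lone-pair bookkeeping are part of the
student's answer and must survive I/O untouched.

Supported formats:

* MDL MOL V2000 and multi-record SDF (read and write). Formal charges use
  ``M  CHG``, radicals ``M  RAD``. Lone pairs are not representable in
  standard V2000, so this package writes a property-line extension::

      M  LNP  2   1   3   2   1

  (same shape as ``M  CHG``: count, then atom-number/value pairs, 1-based).
  Foreign readers ignore unknown ``M`` lines; our reader honors them.
* A structure-editor JSON schema (documented in the README): an ``atoms``
  array with ``element``/``x``/``y``/``charge``/``lonePairs``/``radicals``
  and a ``bonds`` array with ``begin``/``end``/``order``/``stereo``.

Coordinates are carried through (the InChI generator perceives R/S and Z/E
from 2D coordinates plus wedge flags) but play no role in fragmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum

from .errors import (
    MolfileParseError,
    SchemaError,
    StructureValidationError,
    UnsupportedSizeError,
)

__all__ = [
    "Atom",
    "Bond",
    "BondOrder",
    "BondStereo",
    "Molecule",
    "read_molfile",
    "write_molfile",
    "read_sdf",
    "write_sdf",
    "read_editor_json",
    "write_editor_json",
    "kekulized",
]

# Periodic-table symbols accepted by the model (H..Og).
_ELEMENTS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)


class BondOrder(IntEnum):
    SINGLE = 1
    DOUBLE = 2
    TRIPLE = 3
    AROMATIC = 4


class BondStereo(IntEnum):
    """MOL bond-block stereo flag (V2000 column 4 codes)."""

    NONE = 0
    WEDGE = 1
    EITHER = 4
    CIS_TRANS = 3
    HASH = 6


@dataclass
class Atom:
    """One atom. Its index is its position in ``Molecule.atoms`` (0-based).

    ``explicit_hydrogens`` is a hydrogen-count annotation carried by formats
    that store one (editor JSON); hydrogens drawn as their own atoms appear in
    the graph instead and are never counted here.
    """

    element: str
    formal_charge: int = 0
    radical_electrons: int = 0
    lone_pairs: int = 0
    explicit_hydrogens: int = 0
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0

    def __post_init__(self):
        if self.element not in _ELEMENTS:
            raise StructureValidationError(f"unknown element symbol {self.element!r}")
        if not 0 <= self.lone_pairs <= 4:
            raise StructureValidationError(
                f"lone_pairs must be in 0..4, got {self.lone_pairs}"
            )
        if not 0 <= self.radical_electrons <= 3:
            raise StructureValidationError(
                f"radical_electrons must be in 0..3, got {self.radical_electrons}"
            )
        if self.explicit_hydrogens < 0:
            raise StructureValidationError("explicit_hydrogens must be >= 0")


@dataclass
class Bond:
    begin: int
    end: int
    order: BondOrder = BondOrder.SINGLE
    stereo: BondStereo = BondStereo.NONE


@dataclass
class Molecule:
    """A labeled molecular graph; may be disconnected (salts allowed)."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.begin < n) or not (0 <= b.end < n):
                raise StructureValidationError(
                    f"bond {b.begin}-{b.end} references a missing atom "
                    f"(molecule has {n} atoms)"
                )
            if b.begin == b.end:
                raise StructureValidationError(f"self-bond on atom {b.begin}")
            key = (min(b.begin, b.end), max(b.begin, b.end))
            if key in seen:
                raise StructureValidationError(f"duplicate bond {key[0]}-{key[1]}")
            seen.add(key)

    # -- small conveniences used throughout the pipeline -------------------
    @property
    def lone_pair_total(self) -> int:
        return sum(a.lone_pairs for a in self.atoms)

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.begin == i:
                out.append(b.end)
            elif b.end == i:
                out.append(b.begin)
        return out


# ---------------------------------------------------------------------------
# MOL V2000
# ---------------------------------------------------------------------------

# Old-style atom-block charge column codes (superseded by M CHG when present).
_OLD_CHARGE = {1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}
# MDL radical codes <-> unpaired-electron counts (doublet=1, triplet=2).
_RAD_FROM_CODE = {1: 0, 2: 1, 3: 2}
_CODE_FROM_RAD = {1: 2, 2: 3}


def _parse_property_pairs(line: str, lineno: int) -> list[tuple[int, int]]:
    toks = line.split()
    try:
        count = int(toks[2])
        vals = [int(t) for t in toks[3 : 3 + 2 * count]]
        if len(vals) != 2 * count:
            raise ValueError
    except (IndexError, ValueError):
        raise MolfileParseError(
            f"malformed property line (line {lineno}): {line.rstrip()!r}"
        ) from None
    return list(zip(vals[0::2], vals[1::2]))


def read_molfile(text: str) -> Molecule:
    """Parse a single MOL V2000 document into a :class:`Molecule`.

    ``M  CHG`` / ``M  RAD`` / ``M  LNP`` property lines are honored; when a
    ``M  CHG`` or ``M  RAD`` block is present it supersedes the atom-block
    charge column, per the CTfile convention.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileParseError("document too short: no counts line (line 4)")
    counts = lines[3]
    try:
        natoms = int(counts[0:3])
        nbonds = int(counts[3:6])
    except ValueError:
        raise MolfileParseError(
            f"malformed counts line (line 4): {counts.rstrip()!r}"
        ) from None
    if "V3000" in counts:
        raise MolfileParseError("V3000 connection tables are not supported")

    atoms: list[Atom] = []
    old_charges: dict[int, int] = {}
    for i in range(natoms):
        lineno = 5 + i
        try:
            line = lines[4 + i]
            x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
            element = line[31:34].strip()
        except (IndexError, ValueError):
            raise MolfileParseError(
                f"malformed atom line (line {lineno})"
            ) from None
        code = 0
        if len(line) >= 39:
            try:
                code = int(line[36:39])
            except ValueError:
                code = 0
        if code in _OLD_CHARGE:
            old_charges[i] = _OLD_CHARGE[code]
        atoms.append(Atom(element=element, x=x, y=y, z=z))

    bonds: list[Bond] = []
    bond_specs: list[tuple[int, int, int, int]] = []
    for i in range(nbonds):
        lineno = 5 + natoms + i
        try:
            line = lines[4 + natoms + i]
            a, b = int(line[0:3]), int(line[3:6])
            order = int(line[6:9])
            stereo = int(line[9:12]) if len(line) >= 12 and line[9:12].strip() else 0
        except (IndexError, ValueError):
            raise MolfileParseError(
                f"malformed bond line (line {lineno})"
            ) from None
        bond_specs.append((a, b, order, stereo))

    charges: dict[int, int] = {}
    radicals: dict[int, int] = {}
    lone_pairs: dict[int, int] = {}
    saw_chg_or_rad = False
    for off, line in enumerate(lines[4 + natoms + nbonds :]):
        lineno = 5 + natoms + nbonds + off
        if line.startswith("M  END"):
            break
        if line.startswith("M  CHG"):
            saw_chg_or_rad = True
            for a, v in _parse_property_pairs(line, lineno):
                charges[a - 1] = v
        elif line.startswith("M  RAD"):
            saw_chg_or_rad = True
            for a, v in _parse_property_pairs(line, lineno):
                radicals[a - 1] = _RAD_FROM_CODE.get(v, 0)
        elif line.startswith("M  LNP"):
            for a, v in _parse_property_pairs(line, lineno):
                lone_pairs[a - 1] = v

    if not saw_chg_or_rad:
        charges = old_charges
    for idx, atom in enumerate(atoms):
        atoms[idx] = replace(
            atom,
            formal_charge=charges.get(idx, 0),
            radical_electrons=radicals.get(idx, 0),
            lone_pairs=lone_pairs.get(idx, 0),
        )

    for a, b, order, stereo in bond_specs:
        if not (1 <= a <= natoms) or not (1 <= b <= natoms):
            raise StructureValidationError(
                f"bond {a}-{b} references a missing atom (molecule has {natoms} atoms)"
            )
        try:
            bonds.append(
                Bond(a - 1, b - 1, BondOrder(order), BondStereo(stereo))
            )
        except ValueError:
            raise MolfileParseError(
                f"unsupported bond order or stereo flag on bond {a}-{b}"
            ) from None

    name = lines[0].strip() if lines else ""
    return Molecule(atoms=atoms, bonds=bonds, name=name)


def write_molfile(mol: Molecule, include_lone_pairs: bool = True) -> str:
    """Serialize to MOL V2000. Raises for >999 atoms/bonds (format limit)."""
    if len(mol.atoms) > 999 or len(mol.bonds) > 999:
        raise UnsupportedSizeError(
            f"V2000 supports at most 999 atoms/bonds "
            f"(got {len(mol.atoms)} atoms, {len(mol.bonds)} bonds)"
        )
    for i, a in enumerate(mol.atoms):
        if a.radical_electrons not in (0, 1, 2):
            raise StructureValidationError(
                f"radical_electrons={a.radical_electrons} on atom {i} is not "
                "representable in V2000 (doublet/triplet only)"
            )
    out = [mol.name, "  molgrade          2D", ""]
    out.append(f"{len(mol.atoms):>3}{len(mol.bonds):>3}  0  0  0  0  0  0  0  0999 V2000")
    for a in mol.atoms:
        out.append(
            f"{a.x:>10.4f}{a.y:>10.4f}{a.z:>10.4f} {a.element:<3} 0  0  0  0  0  0"
            "  0  0  0  0  0  0"
        )
    for b in mol.bonds:
        out.append(
            f"{b.begin + 1:>3}{b.end + 1:>3}{int(b.order):>3}{int(b.stereo):>3}  0  0  0"
        )

    def _prop(tag: str, pairs: list[tuple[int, int]]) -> None:
        for i in range(0, len(pairs), 8):
            chunk = pairs[i : i + 8]
            body = "".join(f"{a:>4}{v:>4}" for a, v in chunk)
            out.append(f"M  {tag}{len(chunk):>3}{body}")

    _prop("CHG", [(i + 1, a.formal_charge) for i, a in enumerate(mol.atoms) if a.formal_charge])
    _prop("RAD", [(i + 1, _CODE_FROM_RAD[a.radical_electrons])
                  for i, a in enumerate(mol.atoms) if a.radical_electrons])
    if include_lone_pairs:
        _prop("LNP", [(i + 1, a.lone_pairs) for i, a in enumerate(mol.atoms) if a.lone_pairs])
    out.append("M  END")
    return "\n".join(out) + "\n"


def read_sdf(text: str) -> list[Molecule]:
    """Read a multi-record SDF (records separated by ``$$$$``)."""
    mols = []
    for record in text.split("$$$$"):
        if record.strip():
            mols.append(read_molfile(record.lstrip("\n")))
    return mols


def write_sdf(mols: list[Molecule]) -> str:
    return "".join(write_molfile(m) + "$$$$\n" for m in mols)


# ---------------------------------------------------------------------------
# Structure-editor JSON
# ---------------------------------------------------------------------------

_ORDER_FROM_JSON = {1: BondOrder.SINGLE, 2: BondOrder.DOUBLE,
                    3: BondOrder.TRIPLE, 4: BondOrder.AROMATIC}
_STEREO_NAMES = {"none": BondStereo.NONE, "wedge": BondStereo.WEDGE,
                 "hash": BondStereo.HASH, "either": BondStereo.EITHER,
                 "cis_trans": BondStereo.CIS_TRANS}


def read_editor_json(text: str | dict) -> Molecule:
    """Parse the documented structure-editor JSON schema.

    Lone pairs and radicals travel natively here (``lonePairs``/``radicals``
    per atom), unlike MOL where they need property-line extensions.
    """
    try:
        doc = json.loads(text) if isinstance(text, str) else text
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from None
    if not isinstance(doc, dict) or "atoms" not in doc:
        raise SchemaError("missing required 'atoms' array")
    if not isinstance(doc["atoms"], list):
        raise SchemaError("'atoms' must be an array")
    atoms = []
    for i, a in enumerate(doc["atoms"]):
        if "element" not in a:
            raise SchemaError(f"atom {i}: missing 'element'")
        atoms.append(
            Atom(
                element=a["element"],
                formal_charge=int(a.get("charge", 0)),
                radical_electrons=int(a.get("radicals", 0)),
                lone_pairs=int(a.get("lonePairs", 0)),
                explicit_hydrogens=int(a.get("hydrogens", 0)),
                x=float(a.get("x", 0.0)),
                y=float(a.get("y", 0.0)),
                z=float(a.get("z", 0.0)),
            )
        )
    bonds = []
    for i, b in enumerate(doc.get("bonds", [])):
        try:
            begin, end = int(b["begin"]), int(b["end"])
        except (KeyError, TypeError, ValueError):
            raise SchemaError(f"bond {i}: missing or invalid 'begin'/'end'") from None
        order = _ORDER_FROM_JSON.get(int(b.get("order", 1)))
        if order is None:
            raise SchemaError(f"bond {i}: unsupported order {b.get('order')!r}")
        stereo = _STEREO_NAMES.get(str(b.get("stereo", "none")))
        if stereo is None:
            raise SchemaError(f"bond {i}: unsupported stereo {b.get('stereo')!r}")
        bonds.append(Bond(begin, end, order, stereo))
    return Molecule(atoms=atoms, bonds=bonds, name=str(doc.get("name", "")))


def write_editor_json(mol: Molecule) -> str:
    stereo_name = {v: k for k, v in _STEREO_NAMES.items()}
    doc = {
        "name": mol.name,
        "atoms": [
            {
                "element": a.element,
                "x": a.x,
                "y": a.y,
                "charge": a.formal_charge,
                "lonePairs": a.lone_pairs,
                "radicals": a.radical_electrons,
                "hydrogens": a.explicit_hydrogens,
            }
            for a in mol.atoms
        ],
        "bonds": [
            {
                "begin": b.begin,
                "end": b.end,
                "order": int(b.order),
                "stereo": stereo_name[b.stereo],
            }
            for b in mol.bonds
        ],
    }
    return json.dumps(doc, indent=2)


# ---------------------------------------------------------------------------
# Kekulization (delegated to RDKit; lone pairs re-applied afterwards)
# ---------------------------------------------------------------------------

def kekulized(mol: Molecule) -> Molecule:
    """Return a copy with aromatic bonds replaced by alternating single/double.

    Fragment labels need concrete bond orders, so aromatic inputs are
    kekulized before enumeration. Atom order is preserved; lone-pair and
    radical annotations are carried over by index.
    """
    if not any(b.order == BondOrder.AROMATIC for b in mol.bonds):
        return mol
    from rdkit import Chem

    block = write_molfile(mol, include_lone_pairs=False)
    rd = Chem.MolFromMolBlock(block, removeHs=False, sanitize=True)
    if rd is None:
        raise StructureValidationError(
            "aromatic structure could not be kekulized"
        )
    Chem.Kekulize(rd, clearAromaticFlags=True)
    new_bonds = []
    for b in mol.bonds:
        rb = rd.GetBondBetweenAtoms(b.begin, b.end)
        order = BondOrder(int(rb.GetBondTypeAsDouble()))
        new_bonds.append(Bond(b.begin, b.end, order, b.stereo))
    return Molecule(atoms=list(mol.atoms), bonds=new_bonds, name=mol.name)
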