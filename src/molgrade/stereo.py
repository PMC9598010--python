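"""InChI-based stereochemistry comparison.

Stereo is scored on the InChI string, not on wedge bonds directly: the
standard InChI generator canonicalizes atom numbering and perceives R/S and
Z/E from 2D coordinates plus wedges, so two drawings of the same molecule
always yield comparable layers. Generation is delegated to the reference
implementation (via RDKit's bundled InChI library); the layer parsing and
the comparison rule live here.

The rule: the two structures stripped of all stereo layers must be
*identical* (equal core InChI); the score is then the fraction of the
teacher's stereo units — tetrahedral ``/t`` entries plus double-bond ``/b``
entries — whose marks the student reproduced. ``/t`` marks are relative to
the ``/m`` mirror label, so when the two ``/m`` labels differ the student's
marks are compared flipped; a full enantiomer therefore scores 0, not 1.
An undefined mark (``?``) matches only an undefined mark: leaving a center
undrawn is not a wildcard. A structure with no stereo units at all scores 1
when the skeletons match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import InChIParseError, StructureRejectedError
from .structures import Molecule, write_molfile

__all__ = [
    "ComponentStereo",
    "InChIStereoLayers",
    "StereoComparison",
    "make_inchi",
    "split_layers",
    "stereo_score",
]

# Layer prefixes carrying stereo information (b: double bond, t: tetrahedral,
# m: mirror, s: stereo type). /s is parsed but ignored for scoring.
_STEREO_PREFIXES = ("b", "t", "m", "s")

_T_TOKEN = re.compile(r"^(\d+)([+\-?])$")
_B_TOKEN = re.compile(r"^(\d+)-(\d+)([+\-?])$")
_FLIP = {"+": "-", "-": "+", "?": "?"}


@dataclass
class ComponentStereo:
    """Stereo marks of one InChI component (one connected structure)."""

    tetra: dict[int, str] = field(default_factory=dict)
    double_bond: dict[tuple[int, int], str] = field(default_factory=dict)
    mirror: str | None = None

    @property
    def unit_count(self) -> int:
        return len(self.tetra) + len(self.double_bond)


@dataclass
class InChIStereoLayers:
    """An InChI split into its stereo-free core and per-component stereo maps."""

    core: str
    components: list[ComponentStereo] = field(default_factory=list)
    stereo_type: str | None = None  # the /s layer; ignored for scoring

    # Single-component accessors (the overwhelmingly common case).
    @property
    def tetra(self) -> dict[int, str]:
        return self.components[0].tetra if self.components else {}

    @property
    def double_bond(self) -> dict[tuple[int, int], str]:
        return self.components[0].double_bond if self.components else {}

    @property
    def mirror(self) -> str | None:
        return self.components[0].mirror if self.components else None

    @property
    def unit_count(self) -> int:
        return sum(c.unit_count for c in self.components)


@dataclass
class StereoComparison:
    """Counts of matched vs. total teacher stereo units.

    When ``skeletons_identical`` is false the comparison is void and the
    score is forced to 0 — marks on different skeletons are incomparable.
    """

    correct: int
    total: int
    skeletons_identical: bool = True

    def __post_init__(self):
        if self.correct > self.total:
            raise ValueError("correct cannot exceed total")


def make_inchi(mol: Molecule) -> str:
    """Standard InChI of a molecule (reference v1.06 algorithm via RDKit).

    The molecule is serialized to MOL (without the lone-pair extension line:
    lone pairs have no InChI representation) so that stereo perception runs
    on the 2D coordinates and wedge flags exactly as drawn.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.warning")
    block = write_molfile(mol, include_lone_pairs=False)
    rd = Chem.MolFromMolBlock(block, removeHs=False, sanitize=True)
    if rd is None:
        raise StructureRejectedError(
            "structure could not be sanitized for InChI generation"
        )
    inchi = Chem.MolToInchi(rd, treatWarningAsError=False)
    if not inchi:
        raise StructureRejectedError("InChI generation failed for the structure")
    return inchi


def _expand_multiplier(segment: str) -> list[str]:
    """Expand 'n*' component multipliers: '2*3-' -> ['3-', '3-']."""
    out = []
    for comp in segment.split(";"):
        m = re.match(r"^(\d+)\*(.*)$", comp)
        if m:
            out.extend([m.group(2)] * int(m.group(1)))
        else:
            out.append(comp)
    return out


def split_layers(inchi: str) -> InChIStereoLayers:
    """Split an InChI into stereo-free core plus parsed stereo layers.

    The core keeps the original layer order with ``/b``, ``/t``, ``/m``,
    ``/s`` excised, so two InChIs have equal cores iff the underlying
    constitutions (including charges, protonation and isotopes) coincide.
    """
    if not inchi.startswith("InChI="):
        raise InChIParseError(f"not an InChI string: {inchi[:30]!r}")
    segments = inchi[len("InChI="):].split("/")
    core_segments = [segments[0]]
    layers: dict[str, str] = {}
    for seg in segments[1:]:
        if seg and seg[0] in _STEREO_PREFIXES and seg[0] not in layers:
            layers[seg[0]] = seg[1:]
        else:
            core_segments.append(seg)
    core = "InChI=" + "/".join(core_segments)

    t_comps = _expand_multiplier(layers["t"]) if "t" in layers else []
    b_comps = _expand_multiplier(layers["b"]) if "b" in layers else []
    m_chars = list(layers.get("m", ""))
    n_comp = max(len(t_comps), len(b_comps), len(m_chars), 0)

    components = []
    for i in range(n_comp):
        comp = ComponentStereo()
        if i < len(t_comps) and t_comps[i]:
            for tok in t_comps[i].split(","):
                m = _T_TOKEN.match(tok)
                if not m:
                    raise InChIParseError(f"malformed /t token {tok!r}")
                comp.tetra[int(m.group(1))] = m.group(2)
        if i < len(b_comps) and b_comps[i]:
            for tok in b_comps[i].split(","):
                m = _B_TOKEN.match(tok)
                if not m:
                    raise InChIParseError(f"malformed /b token {tok!r}")
                comp.double_bond[(int(m.group(1)), int(m.group(2)))] = m.group(3)
        if i < len(m_chars) and m_chars[i] in "01":
            comp.mirror = m_chars[i]
        components.append(comp)
    return InChIStereoLayers(
        core=core, components=components, stereo_type=layers.get("s")
    )


def stereo_score(teacher: str, student: str) -> tuple[float, StereoComparison]:
    """Fraction of the teacher's stereo units the student drew correctly.

    Returns ``(g_rest, comparison)``. The teacher's unit set defines the
    denominator; student marks at units the teacher left undefined are not
    scored. Non-identical stereo-stripped skeletons score 0 outright.
    """
    t = split_layers(teacher)
    s = split_layers(student)
    total = t.unit_count
    if t.core != s.core:
        return 0.0, StereoComparison(0, total, skeletons_identical=False)
    if total == 0:
        return 1.0, StereoComparison(0, 0, skeletons_identical=True)

    correct = 0
    for i, tc in enumerate(t.components):
        sc = s.components[i] if i < len(s.components) else ComponentStereo()
        flip = (
            tc.mirror is not None
            and sc.mirror is not None
            and tc.mirror != sc.mirror
        )
        for atom, mark in tc.tetra.items():
            smark = sc.tetra.get(atom)
            if smark is None:
                continue
            if flip:
                smark = _FLIP[smark]
            if smark == mark:
                correct += 1
        for pair, mark in tc.double_bond.items():
            if sc.double_bond.get(pair) == mark:
                correct += 1
    return correct / total, StereoComparison(correct, total, skeletons_identical=True)
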