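"""ISIDA-style linear fragment enumeration.

Descriptors here are counts of *sequences*: simple paths of ``min_len`` to
``max_len`` atoms rendered as alternating atom labels and bond-order symbols
(e.g. ``C-C=C``), plus, optionally, per-atom-label counts. Counting — rather
than presence/absence fingerprinting — is what lets the similarity score
notice a single missing lone pair.

Electron bookkeeping enters the descriptor space in one of two ways:

* **pseudo-atom mode** (the default): every lone pair becomes a degree-1
  ``LP`` node bonded to its atom and participates in paths and atom counts
  exactly like a real atom. This is the mode that, combined with the
  dot-product Tanimoto variant, reproduces the partial-credit behavior the
  grader is calibrated to (a Lewis structure of nitrosyl fluoride missing
  one fluorine lone pair scores 0.90 against the complete drawing).
* **decoration mode**: lone pairs annotate the atom label itself
  (``F:3``), so a lone-pair error changes every fragment through that atom.

Formal charges and radicals always decorate the atom label (``O-1``,
``C^1``). Explicit hydrogens are ordinary graph atoms and participate in
paths — hydrogen management is part of the graded answer.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, TextIO

import yaml

from .errors import ConfigurationError, UnsupportedSizeError
from .structures import Atom, BondOrder, Molecule, kekulized

__all__ = [
    "FragmentationScheme",
    "FragmentCountVector",
    "atom_label",
    "enumerate_fragments",
    "brute_force_paths",
    "dump_descriptors",
    "BOND_SYMBOL",
    "LP_LABEL",
]

#: Printable bond-order symbols used inside fragment strings. After
#: kekulization ":" should not survive; it is retained for robustness.
BOND_SYMBOL = {
    BondOrder.SINGLE: "-",
    BondOrder.DOUBLE: "=",
    BondOrder.TRIPLE: "#",
    BondOrder.AROMATIC: ":",
}

#: Label of the lone-pair pseudo-atom.
LP_LABEL = "LP"

#: A sparse fragment count vector: canonical fragment string -> count >= 1.
FragmentCountVector = Counter


@dataclass(frozen=True)
class FragmentationScheme:
    """Configuration of the descriptor space.

    The default — sequences of 2–4 atoms and bonds, colored by formal
    charges, lone pairs and radicals, with atom counts included — is the
    IAB(2–4)FC-style embedding the grading defaults are calibrated against.
    """

    min_len: int = 2
    max_len: int = 4
    use_formal_charge: bool = True
    use_lone_pairs: bool = True
    use_radicals: bool = True
    include_atom_counts: bool = True
    lone_pairs_as_pseudo_atoms: bool = True

    def __post_init__(self):
        if self.min_len < 1:
            raise ConfigurationError(f"min_len must be >= 1, got {self.min_len}")
        if self.max_len < self.min_len:
            raise ConfigurationError(
                f"max_len ({self.max_len}) must be >= min_len ({self.min_len})"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "FragmentationScheme":
        """Load a scheme from a YAML key-value file (see data/default_scheme.yaml)."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"scheme config {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(
                f"unknown scheme keys in {path}: {sorted(unknown)}"
            )
        return cls(**doc)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def atom_label(atom: Atom, scheme: FragmentationScheme) -> str:
    """Deterministic printable label of an atom under the active scheme.

    Grammar: ``element`` + ``{+n|-n}`` (formal charge, if toggled on and
    nonzero) + ``:n`` (lone pairs, decoration mode only) + ``^n`` (radical
    electrons). Toggled-off attributes are omitted.
    """
    parts = [atom.element]
    if scheme.use_formal_charge and atom.formal_charge:
        parts.append(f"{atom.formal_charge:+d}")
    if (
        scheme.use_lone_pairs
        and not scheme.lone_pairs_as_pseudo_atoms
        and atom.lone_pairs
    ):
        parts.append(f":{atom.lone_pairs}")
    if scheme.use_radicals and atom.radical_electrons:
        parts.append(f"^{atom.radical_electrons}")
    return "".join(parts)


def _colored_graph(
    mol: Molecule, scheme: FragmentationScheme
) -> tuple[list[str], dict[int, list[int]], dict[tuple[int, int], str]]:
    """Node labels, adjacency and edge symbols, with LP pseudo-nodes if active."""
    mol = kekulized(mol)
    labels = [atom_label(a, scheme) for a in mol.atoms]
    adj: dict[int, list[int]] = {i: [] for i in range(len(mol.atoms))}
    esym: dict[tuple[int, int], str] = {}
    for b in mol.bonds:
        adj[b.begin].append(b.end)
        adj[b.end].append(b.begin)
        sym = BOND_SYMBOL[b.order]
        esym[(b.begin, b.end)] = sym
        esym[(b.end, b.begin)] = sym
    if scheme.use_lone_pairs and scheme.lone_pairs_as_pseudo_atoms:
        for i, a in enumerate(mol.atoms):
            for _ in range(a.lone_pairs):
                j = len(labels)
                labels.append(LP_LABEL)
                adj[j] = [i]
                adj[i].append(j)
                esym[(i, j)] = esym[(j, i)] = BOND_SYMBOL[BondOrder.SINGLE]
    return labels, adj, esym


def _render(path: tuple[int, ...], labels: list[str],
            esym: dict[tuple[int, int], str]) -> str:
    parts = [labels[path[0]]]
    for u, v in zip(path, path[1:]):
        parts.append(esym[(u, v)])
        parts.append(labels[v])
    return "".join(parts)


def enumerate_fragments(
    mol: Molecule, scheme: FragmentationScheme | None = None
) -> FragmentCountVector:
    """Count all linear fragments of ``mol`` under ``scheme``.

    Each undirected simple path of ``min_len``..``max_len`` atoms contributes
    exactly once under its canonical label — the lexicographic minimum of the
    forward and reversed renderings — and identical paths accumulate
    multiplicity. With ``include_atom_counts``, every node (including lone-
    pair pseudo-nodes) also contributes one count to its atom label.

    Disconnected structures need no special casing: paths never cross
    components, so component vectors add by construction.
    """
    scheme = scheme or FragmentationScheme()
    labels, adj, esym = _colored_graph(mol, scheme)
    counts: FragmentCountVector = Counter()

    if scheme.include_atom_counts:
        for lab in labels:
            counts[lab] += 1

    # Every undirected path of >= 2 atoms is visited once per direction by
    # the DFS below, so directed tallies are exactly twice the undirected
    # ones. min_len == 1 single-atom "paths" coincide with atom counts and
    # are covered above.
    directed: Counter = Counter()
    lo = max(scheme.min_len, 2)

    def extend(path: list[int], visited: set[int]) -> None:
        if lo <= len(path):
            rendered = _render(tuple(path), labels, esym)
            reverse = _render(tuple(reversed(path)), labels, esym)
            directed[min(rendered, reverse)] += 1
        if len(path) == scheme.max_len:
            return
        for nxt in adj[path[-1]]:
            if nxt not in visited:
                path.append(nxt)
                visited.add(nxt)
                extend(path, visited)
                visited.remove(nxt)
                path.pop()

    for start in adj:
        extend([start], {start})
    for key, val in directed.items():
        counts[key] += val // 2
    return counts


def brute_force_paths(
    mol: Molecule, min_len: int = 2, max_len: int = 4
) -> Counter:
    """Exhaustive oracle: all undirected simple paths as atom-index tuples.

    Checks every permutation of every ``k``-subset of atoms for pathness, so
    it is trivially correct and deliberately unrelated to the DFS used by
    :func:`enumerate_fragments`. Refuses molecules over 12 atoms. Lone-pair
    pseudo-nodes are *not* added: this oracle works on the plain graph.
    """
    n = len(mol.atoms)
    if n > 12:
        raise UnsupportedSizeError(f"brute-force oracle limited to 12 atoms, got {n}")
    edges = {(b.begin, b.end) for b in mol.bonds} | {
        (b.end, b.begin) for b in mol.bonds
    }
    out: Counter = Counter()
    for k in range(max(min_len, 2), max_len + 1):
        for perm in itertools.permutations(range(n), k):
            if all((u, v) in edges for u, v in zip(perm, perm[1:])):
                key = min(perm, perm[::-1])
                out[key] += 1
    for key in out:
        out[key] //= 2  # each undirected path appears as both directions
    return out


def dump_descriptors(vec: FragmentCountVector, fh: TextIO) -> None:
    """Write a tab-separated fragment -> count listing (debugging aid)."""
    for key in sorted(vec):
        fh.write(f"{key}\t{vec[key]}\n")
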