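# Methods

## Scope of the model

`molgrade` grades a *drawing*, not a molecule in the abstract. Two drawings
of the same compound that differ in explicit hydrogens or in lone-pair
bookkeeping are different answers and grade differently; this is
intentional, because hydrogen and electron management is usually part of
what the question examines. Conversely, depiction choices that do not change
the labeled graph (coordinates, atom order, bond direction) never affect the
grade: descriptors are canonical in the graph, and stereochemistry is read
from the canonical InChI rather than from raw wedges.

## Fragment descriptor space

A structure is embedded as a sparse count vector over linear fragments:

* every undirected simple path of `min_len`–`max_len` atoms (default 2–4),
  rendered as atom labels interleaved with bond symbols
  (`-`, `=`, `#`, `:`); the canonical key of a path is the lexicographic
  minimum of its forward and reversed rendering, so each undirected path
  contributes exactly once;
* one count per atom label over all atoms (`include_atom_counts`, default
  on).

Atom labels are `element` + `+n`/`-n` (formal charge) + `^n` (radical
electrons); each toggle in the `FragmentationScheme` removes its attribute
from the label, merging features while conserving total count mass. Fragments
are enumerated from the structures at hand — there is no pre-defined
dictionary.

Lone pairs enter the graph in one of two modes:

* **pseudo-atom mode (default)** — each lone pair is a degree-1 `LP` node
  single-bonded to its atom, participating in paths and atom counts. A
  missing lone pair then perturbs only the fragments that touch it, which
  produces gentle, well-scaled penalties for Lewis-structure questions.
* **decoration mode** — lone pairs annotate the atom label (`F:3`), so one
  missing pair relabels the atom and breaks *every* fragment through it.
  This is far more punitive (a single missing fluorine lone pair in F–N=O
  drops the similarity from 0.90 to 0.33) and is kept as an option, not the
  default.

Aromatic input bonds are kekulized (via RDKit) before enumeration, because
fragment strings need concrete bond orders. Rings contribute through their
constituent paths; fragments are simple paths only, so no atom repeats
within one fragment. Disconnected structures are enumerated per component
and the vectors add; nothing strips "salt" fragments.

The enumerator is validated against an intentionally naive oracle
(`brute_force_paths`): exhaustive permutation search over ≤ 12-atom graphs,
checked on 200 random colored graphs per test run plus hand-enumerated
cases (K3, path and star graphs, and the complete hand-derived 20-key
nitrosyl fluoride vector).

## Similarity and calibration

Two count-vector Tanimoto generalizations are implemented:

* `dot`: `a·b / (|a|² + |b|² − a·b)`
* `minmax`: `Σ min(aₖ,bₖ) / Σ max(aₖ,bₖ)`

Both are symmetric, bounded in [0, 1], and reach 1 exactly on identical
vectors. The shipped default is `dot` *combined with* pseudo-atom lone
pairs: this pairing was fixed by calibration against the engine's two
reference partial-credit grades — 0.90 for the nitrosyl fluoride drawing
missing one fluorine lone pair (83/92) and 0.68 for
2,3-dimethyl-1-butene against 2,3-dimethyl-2-butene (69/101). The
`minmax` variant yields 0.82 and 0.56 on the same pairs and decoration-mode
lone pairs yield 0.33 on the first; no other mode×variant combination
reproduces both reference values. The calibration is locked in the
acceptance tests.

With several accepted answers the student is scored against each and the
best pair is kept; ties break to the lowest index so the outcome is
deterministic under answer reordering (the grade itself is order-invariant).

## Stereochemistry

Stereo scoring operates on standard InChI strings (reference v1.06
algorithm, invoked through RDKit) so that atom numbering is canonical and
R/S / Z/E perception from 2D coordinates and wedges is delegated rather
than re-implemented. Two gates must pass before any stereo credit:

1. Tanimoto similarity 1.0 against some accepted answer (tolerance 1e−9,
   guarding float noise only — identical vectors give exactly 1);
2. equality of the stereo-stripped InChI cores (`/b`, `/t`, `/m`, `/s`
   removed), the stricter constitutional identity check.

Both gates exist because they fail in different directions: a missing lone
pair breaks gate 1 but not gate 2 (lone pairs have no InChI
representation), while two stereoisomer answer forms share gate-1 vectors.
All teacher answers tying at similarity 1 are stereo-compared and the best
fraction kept, so a question may accept several anomeric forms of one
skeleton.

The score is `correct / total` over the teacher's stereo units: `/t`
tetrahedral entries plus `/b` double-bond entries, per InChI component.
Comparison rules:

* `/t` marks are relative to the `/m` mirror label; when the two `/m`
  labels differ, the student's marks are compared flipped. A full
  enantiomer therefore scores 0/`total`, not `total`/`total`.
* An undefined mark (`?`) matches only an undefined mark. Leaving a center
  undrawn is not a wildcard — an "anomer undefined" answer is a distinct
  accepted form, not a superset.
* The `/s` layer is parsed but ignored; `/b` marks do not flip with `/m`.
* A structure with no stereo units scores 1 when the skeletons match.
* Student marks at centers the teacher left undefined are not scored; only
  the teacher's unit set defines the denominator. (How extra student marks
  *should* be treated is genuinely open; penalizing them would need a
  convention for the denominator that nothing in the grading model fixes.)

## Grade transform

`g = g_rest^α if g_rest^α ≥ t else 0`, applied after stereo. `α > 0` is the
per-question exigency (α < 1 lenient, α > 1 severe; 1 is neutral) and
`t ∈ [0, 1]` a floor that refuses credit for answers too far off. Defaults
are α = 1, t = 0 — the identity — since any other default would encode a
grading policy the teacher should choose. The transform is monotone in
`g_rest` where nonzero and maps 1 to 1 for every α, so a perfect answer can
never be clipped. All scores are carried at full floating precision;
rounding to two decimals is presentation only.

## Structure I/O

The MOL V2000 reader/writer is implemented in-package because the grading
contract needs three things toolkit readers do not provide: a lone-pair
property-line extension (`M  LNP`, same shape as `M  CHG`), strict
round-trips with no sanitization or hydrogen editing, and parse errors that
name the offending line for the service's 422 responses. Radicals map to
MDL codes doublet=2/triplet=3; `radical_electrons = 3` is storable in the
model and in editor JSON but raises on MOL write rather than being silently
altered. Old-style atom-block charge codes are honored unless an `M  CHG`
block is present, which then supersedes them (CTfile convention).

## Worked-example generators

The fixtures module constructs every graded scenario in code:

* nitrosyl fluoride with full Lewis bookkeeping (F:3, N:1, O:2 lone pairs)
  and the one-pair-short student variant, built atom-by-atom;
* the dehydration products 2,3-dimethyl-2-butene / -1-butene from SMILES,
  no explicit hydrogens;
* the 8 accepted glucose drawings and the erroneous student form. Cyclic
  forms are derived from the verified open-chain D-glucose SMILES by
  re-wiring the ring oxygen with every SMILES neighbor ordering preserved,
  which carries the open-chain configurations over unchanged; 2D
  coordinates and wedges come from RDKit depiction, and the tests assert
  the intended `/t` layer contents rather than trusting the drawing. The
  student inverts one of the four open-chain centers — C2 by default — and
  the 3/4 score is asserted for all four choices, since the identity of
  the wrong center is not part of the scenario.

The generators emulate drawings a structure editor would emit (clean
valences, standard depiction). They do not emulate the mess of real student
input — pathological valences, overlapping atoms, editor-specific JSON
dialects — so passing tests certify the scoring pipeline, not robustness to
arbitrary sketcher output beyond the documented error paths.

## Service

The grading endpoint is a stateless WSGI app: parse, grade, forget.
JWTs are compact HS256 tokens verified with a constant-time signature
comparison; the `iat` claim must lie within a freshness window (default
300 s, 30 s future skew) and the `alg` header must be exactly `HS256` —
`none` and anything else is rejected before signature checking. Failed
authentications log the remote address. Responses carry grades at full
precision, mirroring the library result exactly; rounding is the
presenting side's concern.

## Problem sizes and determinism

All reference computations are desk-scale: molecules of 3–25 atoms,
descriptor vectors of tens of keys, InChI calls in milliseconds. The
property sweeps (200 random graphs for the enumeration oracle, 1000 random
vector pairs for the similarity axioms, 100 JWT tampering trials) use
fixed seeds and complete in seconds; sizes were chosen so the oracle's
permutation search stays trivially exhaustive (≤ 12 atoms). There is no
stochastic component in grading itself: identical inputs always produce
bit-identical grades.

## Known limitations

* Grading is global: no extra weight can be given to a particular
  substructure, and there is no wrong-answer bank with targeted feedback.
* No protonation or tautomer standardization: an answer drawn as the
  conjugate base is a different answer.
* Stereo credit requires an exact skeleton match first; a student with
  perfect stereochemistry on a slightly wrong skeleton receives 0 when
  stereo is required.
* V3000, 3D perception and depiction are out of scope; lone-pair transport
  in MOL relies on the documented `M  LNP` extension, which other software
  will ignore (the editor-JSON path carries them natively).
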