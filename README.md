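# molgrade

Soft grading of chemical structure drawings. When a student is asked to draw
a molecule — a Lewis structure, a reaction product, a sugar with its
stereochemistry — a binary right/wrong comparison wastes most of the
information in the answer. `molgrade` awards partial credit by measuring how
similar the student's drawing is to one or more accepted teacher drawings,
and exposes the whole pipeline as a Python library, a command-line tool and
a stateless JSON-over-HTTP grading service with JWT authentication (the
contract an LMS question plugin needs).

## The scoring model

**Descriptors.** Every structure is embedded as a sparse count vector of
linear fragments: all simple paths of 2–4 atoms, rendered as alternating
atom labels and bond symbols (`C-C=C`), plus per-atom-label counts. Atom
labels carry formal charges and radicals; each lone pair becomes a
degree-1 `LP` pseudo-atom that participates in paths, so electron
bookkeeping is graded alongside connectivity. Explicit hydrogens are
ordinary graph atoms — hydrogen management is part of the answer.

**Similarity.** The raw grade is the count-vector Tanimoto coefficient

```
T(a, b) = a·b / (|a|² + |b|² − a·b)
```

against the most similar accepted answer (a Σmin/Σmax variant is also
available). With several accepted answers, the highest-scoring pair is kept.

**Stereochemistry.** When stereo evaluation is on, the student's structure
must first match an accepted answer exactly (Tanimoto = 1 *and* equal
stereo-stripped InChI), and the grade becomes

```
g_rest = (# correct stereo units) / (# teacher stereo units)
```

comparing tetrahedral `/t` and double-bond `/b` marks of the standard InChI
layers, with the `/m` mirror convention applied (a full enantiomer scores 0).
If the skeletons differ, `g_rest = 0`.

**Grade transform.** The final grade is

```
g = g_rest^α   if g_rest^α ≥ t, else 0
```

with per-question exigency `α` (α < 1 lenient, α > 1 severe) and threshold
`t`.

## Worked example

```python
from molgrade import GradingParams, grade_answer
from molgrade.fixtures import build_nitrosyl_fluoride

teacher = build_nitrosyl_fluoride(complete=True)   # F–N=O, all 6 lone pairs
student = build_nitrosyl_fluoride(complete=False)  # one F lone pair missing

result = grade_answer(student, [teacher], GradingParams(alpha=1.0, threshold=0.0))
print(round(result.grade, 2))   # 0.9
```

The student's vector overlaps the teacher's in 32 of 39 fragment counts;
the dot-product Tanimoto works out to 83/92 ≈ 0.9022, so the forgotten lone
pair costs one point in ten rather than all ten. The same pipeline grades a
minor instead of major dehydration product of 2,3-dimethyl-2-butanol at
0.68, and an open-chain glucose drawing with one inverted stereocenter at
g_rest = 3/4 = 0.75 against the 8-form glucose answer set (see
`examples/`, one script per capability).

From a shell:

```
molgrade fixtures --out /tmp/fx
molgrade grade /tmp/fx/glucose_student.sdf /tmp/fx/glucose_teachers.sdf --stereo
molgrade serve --port 8080 --secret s3cret
```

The service accepts `POST /v1/grade` with an `Authorization: Bearer <JWT>`
header (HMAC-SHA256, shared secret, fresh `iat` claim); request and response
schemas are the pydantic models in `molgrade.service`. Structures travel as
MOL V2000 text or as the editor-JSON schema documented below.

## Formats

* **MOL V2000 / SDF** — read and write. Charges via `M  CHG`, radicals via
  `M  RAD`. Lone pairs are not representable in standard V2000, so molgrade
  uses the property-line extension `M  LNP <n> <atom> <count> ...`
  (1-based atom numbers); foreign readers skip unknown `M` lines.
* **Editor JSON** — `{"atoms": [{"element", "x", "y", "charge",
  "lonePairs", "radicals"}], "bonds": [{"begin", "end", "order",
  "stereo"}]}`; lone pairs and radicals travel natively.

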