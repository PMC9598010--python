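"""Partial credit for an imperfect Lewis structure.

A student asked for the Lewis structure of nitrosyl fluoride (F-N=O) forgets
one of the three lone pairs on the fluorine. Because the descriptors count
lone pairs as graph features, the answer keeps most of its credit instead of
scoring zero.
"""

from molgrade import GradingParams, grade_answer
from molgrade.fixtures import build_nitrosyl_fluoride

teacher = build_nitrosyl_fluoride(complete=True)   # F: 3 LP, N: 1 LP, O: 2 LP
student = build_nitrosyl_fluoride(complete=False)  # fluorine has only 2 LP

result = grade_answer(student, [teacher], GradingParams(alpha=1.0, threshold=0.0))
print(f"similarity = {result.similarity:.4f}")
print(f"grade      = {result.grade:.2f}")
# similarity = 0.9022 — the dot-product Tanimoto between the two fragment
# count vectors (83/92); with alpha=1 and no threshold the grade is the
# similarity itself, presented as 0.90 out of 1.
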