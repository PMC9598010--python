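"""Soft grading of a regioselectivity question.

Asked for the major product of 2,3-dimethyl-2-butanol dehydration, a student
draws the minor (anti-Zaitsev) alkene. The two isomers share most of their
skeleton, so the soft grade reflects partial understanding — and the teacher
can harden it with the exigency exponent or the threshold.
"""

from molgrade import GradingParams, grade_answer
from molgrade.fixtures import build_dehydration_products

major, minor = build_dehydration_products()  # 2,3-dimethyl-2-butene / -1-butene

lenient = grade_answer(minor, [major], GradingParams(alpha=1.0, threshold=0.0))
print(f"grade (alpha=1, t=0):   {lenient.grade:.2f}")

severe = grade_answer(minor, [major], GradingParams(alpha=2.0, threshold=0.0))
print(f"grade (alpha=2, t=0):   {severe.grade:.2f}")

cutoff = grade_answer(minor, [major], GradingParams(alpha=1.0, threshold=0.7))
print(f"grade (alpha=1, t=0.7): {cutoff.grade:.2f}")
# 0.68 raw; squaring drops it to 0.47; a threshold of 0.7 zeroes it outright.
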