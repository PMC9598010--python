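"""Stereochemistry scoring against a multi-answer question.

"What is the structure of glucose?" admits 8 correct drawings: two
open-chain forms (with and without the explicit aldehyde hydrogen) and the
alpha/beta/undefined anomers of the furanose and pyranose rings. A student
draws the open chain with one of the four stereocenters inverted: the
skeleton matches one accepted answer exactly, and 3 of its 4 tetrahedral
centers are correct.
"""

from molgrade import GradingParams, grade_answer
from molgrade.fixtures import build_glucose_forms

fixture = build_glucose_forms(student_inverted_center=2)

result = grade_answer(
    fixture.student, fixture.teachers, GradingParams(stereo_required=True)
)
matched = fixture.teacher_names[result.matched_index]
print(f"matched teacher form : {matched}")
print(f"stereo units correct : {result.stereo.correct}/{result.stereo.total}")
print(f"g_rest               : {result.g_rest}")
# matched form: open_explicit_h; 3/4 centers correct; g_rest = 0.75 — the
# fraction of InChI /t-layer marks the student reproduced.
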