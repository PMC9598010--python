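"""Grade orchestration: best-match similarity, optional stereo, grade transform.

The pipeline awards partial credit in two stages. First the raw grade
``g_rest``: the best Tanimoto similarity between the student's fragment
count vector and each accepted teacher answer — or, when stereochemistry is
evaluated, the fraction of correctly drawn stereo units, which is only
defined (and only nonzero) when the student's structure is constitutionally
identical to an accepted answer. Second the per-question transform

    g = g_rest ** alpha   if g_rest ** alpha >= t, else 0

where the exigency exponent ``alpha`` makes grading more lenient (< 1) or
more severe (> 1) and the threshold ``t`` refuses credit for answers too far
from acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, MolGradeError, StructureRejectedError
from .fragmenter import FragmentCountVector, FragmentationScheme, enumerate_fragments
from .similarity import DEFAULT_VARIANT, TanimotoVariant, best_match, tanimoto
from .stereo import StereoComparison, make_inchi, stereo_score
from .structures import Molecule

__all__ = ["GradingParams", "GradeResult", "compute_g_rest", "apply_transform",
           "grade_answer", "SIMILARITY_ONE_TOL"]

#: Tolerance on the "similarity = 1" gate before stereo comparison. Identical
#: count vectors give exactly 1.0 in both Tanimoto variants; this only guards
#: float noise.
SIMILARITY_ONE_TOL = 1e-9


@dataclass(frozen=True)
class GradingParams:
    """Per-question grading knobs (they may differ from question to question)."""

    alpha: float = 1.0
    threshold: float = 0.0
    stereo_required: bool = False
    scheme: FragmentationScheme = field(default_factory=FragmentationScheme)
    variant: TanimotoVariant = DEFAULT_VARIANT

    def __post_init__(self):
        if not self.alpha > 0:
            raise ConfigurationError(f"alpha must be > 0, got {self.alpha}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError(
                f"threshold must be in [0, 1], got {self.threshold}"
            )


@dataclass
class GradeResult:
    """Full grading outcome, at floating precision.

    ``similarity`` is the best Tanimoto score; ``g_rest`` equals it when
    stereo is off, and the stereo fraction otherwise. Rounding to two
    decimals is presentation only (see :meth:`rounded`).
    """

    g_rest: float
    grade: float
    matched_index: int
    similarity: float
    stereo: StereoComparison | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "grade": self.grade,
            "g_rest": self.g_rest,
            "matched_index": self.matched_index,
            "similarity": self.similarity,
            "stereo_detail": (
                None
                if self.stereo is None
                else {
                    "correct": self.stereo.correct,
                    "total": self.stereo.total,
                    "skeletons_identical": self.stereo.skeletons_identical,
                }
            ),
        }

    def rounded(self, ndigits: int = 2) -> dict:
        out = self.to_dict()
        out["grade"] = round(out["grade"], ndigits)
        out["g_rest"] = round(out["g_rest"], ndigits)
        return out


def _vector(mol: Molecule, scheme: FragmentationScheme, side: str) -> FragmentCountVector:
    try:
        return enumerate_fragments(mol, scheme)
    except MolGradeError as exc:
        raise StructureRejectedError(str(exc), side=side) from exc


def compute_g_rest(
    student: Molecule,
    teachers: list[Molecule],
    params: GradingParams | None = None,
) -> tuple[float, int, dict]:
    """Raw grade, matched teacher index, and a diagnostic breakdown.

    Without stereo, ``g_rest`` is the best-match Tanimoto score. With
    stereo, two gates apply before any credit: the Tanimoto score against
    some accepted answer must be 1 (identical descriptor vectors) *and* the
    stereo-stripped InChIs must coincide; all answers tying at similarity 1
    (e.g. anomeric variants sharing one skeleton) are stereo-compared and
    the best fraction is kept.
    """
    params = params or GradingParams()
    if not teachers:
        raise ConfigurationError("at least one teacher answer is required")
    sv = _vector(student, params.scheme, "student")
    tvs = [_vector(t, params.scheme, f"teacher[{k}]") for k, t in enumerate(teachers)]
    best_idx, best_score = best_match(sv, tvs, params.variant)
    diagnostics: dict = {
        "similarity": best_score,
        "matched_index": best_idx,
        "all_scores": [tanimoto(sv, tv, params.variant) for tv in tvs],
        "stereo": None,
    }
    if not params.stereo_required:
        return best_score, best_idx, diagnostics

    ties = [
        i for i, s in enumerate(diagnostics["all_scores"])
        if s >= 1.0 - SIMILARITY_ONE_TOL
    ]
    diagnostics["similarity_gate_passed"] = bool(ties)
    if not ties:
        diagnostics["stereo"] = StereoComparison(0, 0, skeletons_identical=False)
        return 0.0, best_idx, diagnostics

    try:
        student_inchi = make_inchi(student)
    except StructureRejectedError as exc:
        raise StructureRejectedError(str(exc), side="student") from exc
    best_g, best_i, best_cmp = 0.0, ties[0], None
    for i in ties:
        try:
            teacher_inchi = make_inchi(teachers[i])
        except StructureRejectedError as exc:
            raise StructureRejectedError(str(exc), side=f"teacher[{i}]") from exc
        g, cmp_ = stereo_score(teacher_inchi, student_inchi)
        if best_cmp is None or g > best_g:
            best_g, best_i, best_cmp = g, i, cmp_
    diagnostics["stereo"] = best_cmp
    diagnostics["matched_index"] = best_i
    return best_g, best_i, diagnostics


def apply_transform(g_rest: float, params: GradingParams) -> float:
    """Pure grade transform: exponent then threshold clamp."""
    if not 0.0 <= g_rest <= 1.0:
        raise ConfigurationError(f"g_rest must be in [0, 1], got {g_rest}")
    g = g_rest ** params.alpha
    return g if g >= params.threshold else 0.0


def grade_answer(
    student: Molecule,
    teachers: list[Molecule],
    params: GradingParams | None = None,
) -> GradeResult:
    """Grade one student structure against the accepted teacher answers."""
    params = params or GradingParams()
    g_rest, idx, diagnostics = compute_g_rest(student, teachers, params)
    return GradeResult(
        g_rest=g_rest,
        grade=apply_transform(g_rest, params),
        matched_index=idx,
        similarity=diagnostics["similarity"],
        stereo=diagnostics.get("stereo"),
        diagnostics=diagnostics,
    )
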