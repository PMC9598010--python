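"""Tanimoto similarity between fragment count vectors.

Two count-vector generalizations of the Tanimoto coefficient are provided:

* ``"dot"`` (default): ``a·b / (|a|² + |b|² − a·b)`` — the continuous
  Tanimoto on raw counts. This is the variant the grading defaults are
  calibrated to; with lone pairs as pseudo-atoms it reproduces the engine's
  reference partial-credit grades (0.90 for a single missing lone pair on
  nitrosyl fluoride, 0.68 for the minor vs. major butene).
* ``"minmax"``: ``Σ min(aₖ,bₖ) / Σ max(aₖ,bₖ)``.

Both are symmetric, lie in [0, 1], and equal 1 exactly when the vectors are
identical. Scores are carried at full floating precision; rounding to two
decimals happens only at presentation.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Literal, Sequence

from .errors import ConfigurationError, UndefinedSimilarityError

__all__ = ["tanimoto", "best_match", "TanimotoVariant", "DEFAULT_VARIANT"]

TanimotoVariant = Literal["dot", "minmax"]
DEFAULT_VARIANT: TanimotoVariant = "dot"


def tanimoto(a: Counter, b: Counter, variant: TanimotoVariant = DEFAULT_VARIANT) -> float:
    """Similarity in [0, 1]; raises if both vectors are empty.

    An all-empty pair carries no information (the caller must treat the
    structure pair as invalid) — a single empty side simply scores 0.
    """
    if not a and not b:
        raise UndefinedSimilarityError(
            "similarity undefined: both fragment count vectors are empty"
        )
    if variant == "minmax":
        num = sum(min(a[k], b[k]) for k in a.keys() & b.keys())
        den = sum(a.values()) + sum(b.values()) - num
        return num / den
    if variant == "dot":
        num = sum(a[k] * b[k] for k in a.keys() & b.keys())
        den = (
            sum(v * v for v in a.values())
            + sum(v * v for v in b.values())
            - num
        )
        return num / den
    raise ConfigurationError(f"unknown Tanimoto variant {variant!r}")


def best_match(
    student: Counter,
    teachers: Sequence[Counter],
    variant: TanimotoVariant = DEFAULT_VARIANT,
) -> tuple[int, float]:
    """Index and score of the teacher vector most similar to the student's.

    Ties are broken by the lowest index (the first accepted answer wins).
    """
    if not teachers:
        raise ConfigurationError("at least one teacher answer is required")
    best_idx, best_score = 0, -1.0
    for i, t in enumerate(teachers):
        score = tanimoto(student, t, variant)
        if score > best_score:
            best_idx, best_score = i, score
    return best_idx, best_score
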