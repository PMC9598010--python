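"""Exception hierarchy for the grading pipeline.

Every error raised by this package derives from :class:`MolGradeError`, so
callers (the CLI and the grading service) can map failures to exit codes and
HTTP statuses without enumerating causes.
"""


class MolGradeError(Exception):
    """Base class for all molgrade errors."""


class MolfileParseError(MolGradeError, ValueError):
    """A MOL/SDF document is syntactically invalid; the message names the line."""


class StructureValidationError(MolGradeError, ValueError):
    """A structure violates the molecule model (bad bond indices, duplicates, ...)."""


class SchemaError(MolGradeError, ValueError):
    """An editor-JSON document does not match the documented schema."""


class UnsupportedSizeError(MolGradeError, ValueError):
    """The structure exceeds a hard format or oracle size limit."""


class InChIParseError(MolGradeError, ValueError):
    """An InChI string or one of its layer tokens could not be parsed."""


class StructureRejectedError(MolGradeError):
    """A structure was rejected downstream (sanitization or InChI generation).

    ``side`` identifies which input failed: ``"student"`` or ``"teacher[k]"``.
    """

    def __init__(self, message: str, side: str | None = None):
        super().__init__(message if side is None else f"{side}: {message}")
        self.side = side


class UndefinedSimilarityError(MolGradeError, ValueError):
    """Tanimoto similarity is undefined (both count vectors empty)."""


class ConfigurationError(MolGradeError, ValueError):
    """Invalid grading parameters (empty teacher list, alpha <= 0, ...)."""


class AuthenticationError(MolGradeError):
    """A JWT failed verification (bad signature, stale, malformed)."""
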