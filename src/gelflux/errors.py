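"""Exception hierarchy.

User-facing input problems derive from :class:`UserInputError` so the CLI can
map them to exit code 1; anything else is an internal error (exit code 2).
"""


class GelfluxError(Exception):
    """Base class for all package errors."""


class UserInputError(GelfluxError, ValueError):
    """Invalid argument or configuration supplied by the caller."""


class UnitError(UserInputError):
    """Arithmetic attempted between flux records carrying different units."""


class SchemaError(UserInputError):
    """A delimited input table violates the documented column schema."""


class ConstantColumnError(UserInputError):
    """Min-max normalisation or rank correlation of a constant vector."""


class TranslationLossError(GelfluxError):
    """Integrated flux loss too large to be explained by rigid translation."""


class StageError(GelfluxError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
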