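"""Exception hierarchy.

Input/validation problems and computation problems are kept distinct so the
command-line layer can map them to different exit codes (2 and 3).
"""


class CrowdGradeError(Exception):
    """Base class for all package errors."""


class InputError(CrowdGradeError):
    """Invalid user input: schema, validation, alignment, domain, config."""


class ComputationError(CrowdGradeError):
    """A well-formed request whose answer is undefined (e.g. degenerate AUC)."""


class SchemaError(InputError):
    """A required column is missing or a file cannot be parsed."""


class ValidationError(InputError):
    """A value violates a domain invariant (bad grade code, negative duration)."""


class AlignmentError(InputError):
    """Two tables that must cover the same image set do not."""


class DomainError(InputError):
    """A numeric argument lies outside its mathematical domain."""


class EmptyInputError(InputError):
    """An operation that needs at least one element received none."""


class SpecError(InputError):
    """An invalid simulation specification (mixture weights, sizes)."""


class SamplingError(InputError):
    """A subsample was requested that the pool cannot provide."""


class UndefinedAUCError(ComputationError):
    """ROC AUC is undefined: one of the truth classes is empty."""
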