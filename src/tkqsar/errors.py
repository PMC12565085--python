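"""Error taxonomy shared across the toolkit.

Every failure mode named in a module contract maps to one exception class
carrying a stable ``code`` string, so CLI exit codes and curation exclusion
reasons stay machine-readable.
"""

from __future__ import annotations


class TkqsarError(Exception):
    """Base class; ``code`` is a stable machine-readable identifier."""

    code = "TKQSAR_ERROR"
    exit_code = 1

    def __init__(self, message: str = ""):
        super().__init__(message or self.code)


class UnparseableSmilesError(TkqsarError):
    code = "UNPARSEABLE_SMILES"
    exit_code = 3


class MixedEndpointsError(TkqsarError):
    code = "MIXED_ENDPOINTS"
    exit_code = 4


class EmptyInputError(TkqsarError):
    code = "EMPTY_INPUT"
    exit_code = 5


class NonPositiveValueError(TkqsarError):
    code = "NONPOSITIVE_VALUE"
    exit_code = 6


class SchemeMismatchError(TkqsarError):
    code = "SCHEME_MISMATCH"
    exit_code = 7


class BackendUnavailableError(TkqsarError):
    code = "BACKEND_UNAVAILABLE"
    exit_code = 8


class AllColumnsRemovedError(TkqsarError):
    code = "ALL_COLUMNS_REMOVED"
    exit_code = 9


class DegenerateTargetError(TkqsarError):
    code = "DEGENERATE_TARGET"
    exit_code = 10


class UnknownLearnerError(TkqsarError):
    code = "UNKNOWN_LEARNER"
    exit_code = 11


class ZeroTrainVarianceError(TkqsarError):
    code = "ZERO_TRAIN_VARIANCE"
    exit_code = 12


class UndefinedClassError(TkqsarError):
    code = "UNDEFINED_CLASS"
    exit_code = 13


class LengthMismatchError(TkqsarError):
    code = "LENGTH_MISMATCH"
    exit_code = 14


class TrainTooSmallError(TkqsarError):
    code = "TRAIN_TOO_SMALL"
    exit_code = 15


class SingularMatrixError(TkqsarError):
    code = "SINGULAR_MATRIX"
    exit_code = 16


class InvalidCountsError(TkqsarError):
    code = "INVALID_COUNTS"
    exit_code = 17


class MissingPropertyError(TkqsarError):
    code = "MISSING_PROPERTY"
    exit_code = 18


class ConfigInvalidError(TkqsarError):
    code = "CONFIG_INVALID"
    exit_code = 2
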