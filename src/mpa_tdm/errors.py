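"""Typed errors raised across the package.

Every malformed input raises one of these; nothing fails silently.
"""


class MpaTdmError(Exception):
    """Base class for all package errors."""


class SchemaError(MpaTdmError):
    """A CSV table is missing a required column or has an unusable header."""


class ValidationError(MpaTdmError):
    """A record violates a data-model invariant; names the patient and rule."""


class DomainError(MpaTdmError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class CoverageError(MpaTdmError):
    """A concentration-time profile does not cover the required window."""


class InsufficientDataError(MpaTdmError):
    """Too few observations to evaluate the operation."""


class CalibrationError(MpaTdmError):
    """Simulator calibration cannot reach the requested target."""


class PipelineError(MpaTdmError):
    """A pipeline stage failed; the message names the stage."""
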