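"""Exception hierarchy.

Input problems (malformed tables, missing fields, misaligned patient ids)
raise :class:`InputError` subclasses; calling an operation out of order or
on data that violates its preconditions raises :class:`StateError`
subclasses.  Statistics whose denominator is empty are *not* errors — they
are reported as undefined (NaN) with a flag.
"""


class CbsAmyloidError(Exception):
    """Base class for all package errors."""


class InputError(CbsAmyloidError, ValueError):
    """Malformed or inconsistent input data."""


class MissingFieldError(InputError):
    """A required field/column is absent; names the offending field."""

    def __init__(self, field: str, context: str = ""):
        self.field = field
        msg = f"missing required field {field!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class ExclusivityError(InputError):
    """The two mutually exclusive cognitive-profile indicators are both set."""


class AlignmentError(InputError):
    """Prediction and reference patient-id sets differ; lists offenders."""

    def __init__(self, only_left, only_right):
        self.only_left = sorted(only_left)
        self.only_right = sorted(only_right)
        super().__init__(
            "patient ids do not align: "
            f"only in predictions {self.only_left}, only in reference {self.only_right}"
        )


class InvalidReferenceError(InputError):
    """Non-positive reference-region uptake (e.g. pons mean <= 0)."""


class DegenerateReferenceError(InputError):
    """Control reference with non-positive SD — Z-scores undefined."""


class InvalidUptakeError(InputError):
    """Non-positive regional uptake where positivity is required."""


class InsufficientDataError(InputError):
    """Too few frames/points for a fit."""


class StateError(CbsAmyloidError, RuntimeError):
    """Operation invoked on a patient/record that fails its precondition."""


class CoreIneligibleError(StateError):
    """Variant evaluation requested for a patient failing core criteria."""


class NoVariantError(StateError):
    """Adjudication requested when neither variant's criteria are met."""


class SpecError(InputError):
    """Infeasible synthetic-cohort specification."""
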