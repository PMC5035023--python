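"""Exception hierarchy.

Validation errors signal contract violations in caller-supplied values,
structural errors signal geometrically incompatible inputs (e.g. water and
fat grids that do not match), and flagged errors carry a partial result or
diagnostic payload for conditions the pipeline can report on but not fix.
"""


class DixonError(Exception):
    """Base class for all package errors."""


class ValidationError(DixonError, ValueError):
    """A supplied value violates a documented precondition."""


class StructuralError(DixonError):
    """Input images are structurally incompatible (grid/geometry mismatch)."""


class AdiposeReferenceError(DixonError):
    """No pure adipose tissue reference could be found; calibration cannot proceed."""


class BiasFieldError(DixonError):
    """The adipose mask is too sparse to constrain the bias field."""


class RegistrationError(DixonError):
    """Registration did not converge; carries the best field found so far."""

    def __init__(self, message, field=None):
        super().__init__(message)
        self.field = field
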