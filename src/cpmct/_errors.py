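"""Exception taxonomy shared across the package.

All package-specific failures derive from :class:`CpmctError` so callers can
catch one base class; the subclasses distinguish input problems from model
fitting problems and numeric-accuracy problems (the CLI maps these to
distinct exit codes).
"""


class CpmctError(Exception):
    """Base class for all cpmct errors."""


class InputSchemaError(CpmctError):
    """A required column or field is missing or malformed."""


class DomainError(CpmctError):
    """A value is outside the mathematical domain of an operation."""


class NestingViolationError(InputSchemaError):
    """A cluster identifier occurs at more than one time point."""


class SpecError(CpmctError):
    """A scenario or contrast specification is internally inconsistent."""


class UnderDeterminedError(CpmctError):
    """Fewer observations than fixed-effect parameters."""


class DegenerateDataError(CpmctError):
    """Data carry no usable variance for the requested fit."""


class ContractError(CpmctError):
    """Objects passed to an operation do not satisfy its contract."""


class DegenerateContrastError(ContractError):
    """A contrast row has (numerically) zero variance."""


class NumericAccuracyWarning(UserWarning):
    """The requested numeric tolerance could not be reached."""
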