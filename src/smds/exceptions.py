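"""Exception hierarchy for the smds package."""


class SmdsError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SmdsError, ValueError):
    """A physical or algorithmic parameter is out of its valid range."""


class InvalidInputError(SmdsError, ValueError):
    """An input data structure violates its contract (empty, unsorted, ...)."""


class AmbiguityError(InvalidInputError):
    """Inputs are individually valid but jointly ambiguous (e.g. duplicate position ids)."""


class SolverConfigError(SmdsError):
    """The advection-diffusion solver configuration is unusable; carries a diagnostic."""


class OutOfRangeError(InvalidParameterError):
    """A requested value lies outside a tabulated grid; message names the bounds."""


class NoSignalError(SmdsError):
    """A profile contains no usable signal to fit."""


class DegenerateFitError(SmdsError):
    """A fit has a flat or non-convex minimum; no uncertainty can be assigned."""


class FitFailureError(SmdsError):
    """An iterative fit failed to converge; message carries optimizer diagnostics."""


class DegenerateStatisticsError(SmdsError):
    """Summary statistics of a trace are degenerate (e.g. zero variance)."""


class NoBroadeningError(SmdsError):
    """No diffusive broadening beyond the reference width; Fick fit impossible."""


class ConfigurationRequiredError(SmdsError):
    """A quantity that must never be defaulted silently was not supplied."""


class UnidentifiableError(FitFailureError):
    """The data do not constrain the parameter of interest (e.g. flat isotherm)."""
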