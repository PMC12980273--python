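"""Exception hierarchy.

``exit_code`` groups errors for the command line: configuration problems
exit with 2, malformed or degenerate inputs with 3, numeric/fit failures
with 4.
"""


class PharmEEGError(Exception):
    """Base class for all pharmeeg errors."""

    exit_code = 1


class ConfigurationError(PharmEEGError):
    """Invalid parameter, band scheme, signature or run configuration."""

    exit_code = 2


class InputError(PharmEEGError):
    """Input data violates a precondition (too short, non-finite, ...)."""

    exit_code = 3


class FormatError(InputError):
    """A file could not be parsed or fails validation; names the offender."""


class SchemaError(FormatError):
    """Feature/column schema mismatch between artefacts."""


class DegenerateInputError(InputError):
    """Mathematically degenerate input (zero spectrum, zero baseline...)."""


class NumericError(PharmEEGError):
    exit_code = 4


class FitError(NumericError):
    """Model fitting failed (too few records, singleton class, ...)."""
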