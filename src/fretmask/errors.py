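"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`ConfigError` -> 2, any other
:class:`FretmaskError` -> 3.
"""


class FretmaskError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FretmaskError):
    """Invalid configuration or parameter set."""


class DataError(FretmaskError):
    """Malformed, inconsistent, or out-of-range input data."""


class ThresholdError(DataError):
    """Threshold could not be computed (e.g. constant stack under Otsu)."""


class NormalizationError(DataError):
    """Baseline normalization impossible (empty or zero-mean baseline)."""


class FitError(DataError):
    """A model fit failed or the data carry no usable response.

    Carries a ``diagnostics`` dict describing why (residuals, response
    range, parameter bounds hit, ...).
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
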