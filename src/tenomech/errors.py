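"""Exception hierarchy for the tenomech pipeline."""


class TenomechError(Exception):
    """Base class for all tenomech errors."""


class InvalidParameterError(TenomechError, ValueError):
    """A physical or statistical parameter violates its constraints."""


class ConfigurationError(TenomechError, ValueError):
    """A configuration value or required input is missing or inconsistent."""


class FormatError(TenomechError, ValueError):
    """A file does not conform to the documented TSV/CSV dialect."""


class NoLoadingError(TenomechError):
    """An indentation record contains no monotone advance of the base."""


class NoContactError(TenomechError):
    """The force signal never rises above the noise floor: the tip did not
    touch the sample."""


class InsufficientDepthError(TenomechError):
    """The indentation never reaches enough of the fit window to support a
    Hertz fit."""


class InsufficientHoldError(TenomechError):
    """The hold phase is shorter than the requested relaxation evaluation
    time."""


class StageError(TenomechError):
    """A pipeline stage failed; the message names the stage."""
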