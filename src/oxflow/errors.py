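"""Exception hierarchy shared across the pipeline."""


class OxflowError(Exception):
    """Base class for all package-specific errors."""


class ExtrapolationError(OxflowError):
    """A requested wavelength grid falls outside the tabulated span."""


class InvalidInputError(OxflowError):
    """Input violates a documented precondition."""


class FitError(OxflowError):
    """An optimisation stage failed in a way that cannot be flagged."""


class ConfigError(OxflowError):
    """Configuration file failed validation; message names the field."""
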