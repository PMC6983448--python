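"""Exception types shared across the package."""


class CfscreenError(Exception):
    """Base class for package errors."""


class ConfigurationError(CfscreenError, ValueError):
    """A configuration value is outside its valid range; the message names the field."""


class DataError(CfscreenError, ValueError):
    """Input tables are inconsistent (missing outcomes, cohort/set mismatch, ...)."""
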