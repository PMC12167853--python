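"""Exception hierarchy shared across the package."""


class EabsimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EabsimError, ValueError):
    """A scalar parameter is outside its mathematical domain."""


class ValidationError(EabsimError, ValueError):
    """A composite object (spec, config, schedule) violates its contract."""


class SequencingError(EabsimError, RuntimeError):
    """The annual event loop was driven past its horizon or out of order."""


class ConfigError(EabsimError, ValueError):
    """A configuration file could not be interpreted."""
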