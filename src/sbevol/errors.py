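"""Exception hierarchy."""


class SbevolError(Exception):
    """Base class for package errors."""


class ConfigError(SbevolError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(SbevolError, ValueError):
    """Malformed on-disk input."""


class UsageError(SbevolError, ValueError):
    """Operation called with arguments outside its contract."""


class ComputationError(SbevolError, ValueError):
    """Input is syntactically valid but the computation is undefined on it."""
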