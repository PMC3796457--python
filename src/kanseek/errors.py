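"""Exception hierarchy shared across the pipeline stages."""


class KanseekError(Exception):
    """Base class for every error raised by this package."""


class FormatError(KanseekError):
    """A file could not be parsed; message names the offending line/cell."""


class ValidationError(KanseekError):
    """Parsed data violates a structural invariant."""


class ConfigError(KanseekError):
    """An option or configuration value is invalid or infeasible."""
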