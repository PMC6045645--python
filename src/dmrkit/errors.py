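"""Exception hierarchy shared across dmrkit modules."""


class DmrkitError(Exception):
    """Base class for all dmrkit-specific errors."""


class FormatError(DmrkitError, ValueError):
    """A file violated the expected on-disk dialect (names the offending line)."""


class ValidationError(DmrkitError, ValueError):
    """A record or value violated a domain invariant."""


class DuplicateRecordError(ValidationError):
    """Two records claim the same strand-specific cytosine."""


class NotFittableError(DmrkitError, ValueError):
    """A model fit was requested on data that carries no information (all N=0)."""


class ConfigError(DmrkitError, ValueError):
    """A pipeline configuration file is malformed or out of range."""


class PipelineError(DmrkitError, RuntimeError):
    """An end-to-end pipeline stage failed."""
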