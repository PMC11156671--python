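"""Exception hierarchy shared across the pipeline stages."""


class VocalStmError(Exception):
    """Base class for all package errors."""


class ParameterError(VocalStmError, ValueError):
    """An argument or configuration value is invalid."""


class DataError(VocalStmError, ValueError):
    """Input data are degenerate or unusable (empty, too short, constant)."""


class PairingError(VocalStmError, ValueError):
    """Two vocalizations cannot form a within-speaker song/speech pair."""


class DependencyError(VocalStmError, RuntimeError):
    """A pipeline stage was requested before its upstream product exists."""
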