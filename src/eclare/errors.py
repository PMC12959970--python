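"""Exception hierarchy.

Exit-code mapping in the CLI distinguishes data errors (bad volumes, files)
from configuration errors (bad flags, unsupported kernels).
"""


class EclareError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EclareError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(EclareError, ValueError):
    """An unsupported or inconsistent configuration was requested."""


class DataError(EclareError, ValueError):
    """Input data cannot support the requested operation (too small, degenerate)."""


class FormatError(EclareError, ValueError):
    """A file could not be parsed in its expected format."""


class TrainingDivergedError(EclareError, RuntimeError):
    """Optimization produced a non-finite loss."""
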