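"""Exception hierarchy for the pipeline."""


class GatefepError(Exception):
    """Base class for all package errors."""


class ParseError(GatefepError):
    """A file could not be parsed (malformed row, truncated record, ...)."""


class FormatError(GatefepError):
    """Unrecognized or unsupported file format."""


class ConfigurationError(GatefepError):
    """Invalid configuration or generator/grid parameters."""


class InputError(GatefepError):
    """Inconsistent or invalid in-memory inputs to an operation."""


class SelectionError(GatefepError):
    """An atom/residue selection could not be satisfied."""


class AnalysisError(GatefepError):
    """An analysis is undefined on the given data (empty bins, no minimum, ...)."""


class ConvergenceError(GatefepError):
    """An iterative solver failed to converge within its budget."""
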