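"""Exception hierarchy for landmark/network analysis failures."""


class McnetError(Exception):
    """Base class for all package errors."""


class ParseError(McnetError):
    """A file record could not be parsed; message names the offending line."""


class StructureError(McnetError):
    """Input violates a structural invariant (landmark counts, duplicates, labels)."""


class DegenerateConfigurationError(McnetError):
    """A landmark configuration is degenerate (e.g. all points coincident)."""


class ConvergenceError(McnetError):
    """Iterative superimposition failed to converge; message reports the residual."""


class MismatchError(McnetError):
    """Two objects that must describe the same specimens do not."""


class DesignError(McnetError):
    """Replicate design unsuitable for the requested variance decomposition."""


class UndefinedCorrelationError(McnetError):
    """Rv coefficient undefined (zero-variance block)."""
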