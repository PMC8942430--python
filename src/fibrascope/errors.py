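"""Exception hierarchy shared across the pipeline stages."""


class FibrascopeError(Exception):
    """Base class for all package-specific errors."""


class SizingError(FibrascopeError, ValueError):
    """Raised when a generator request cannot satisfy structural invariants."""


class CatalogError(FibrascopeError, ValueError):
    """Raised when a gene catalog violates a structural requirement."""


class ReferenceError_(FibrascopeError, KeyError):
    """Raised when an identifier does not resolve against its reference set."""


class StageError(FibrascopeError, ValueError):
    """Raised when a matrix of the wrong processing stage is supplied."""


class DegenerateDataError(FibrascopeError, ValueError):
    """Raised when data carry no usable signal (e.g. all values tied)."""
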