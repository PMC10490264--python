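"""Exception hierarchy used across the pipeline.

Every stage raises a subclass of :class:`HomeoscopeError`, so callers (and the
CLI) can catch one type and still report the offending stage.
"""


class HomeoscopeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HomeoscopeError):
    """An invalid simulation or pipeline configuration."""


class FormatError(HomeoscopeError):
    """A malformed input file; the message names the offending row."""


class ConsistencyError(HomeoscopeError):
    """Cross-file or cross-table inconsistency (ids that do not resolve, ...)."""


class ContractError(HomeoscopeError):
    """A statistical routine was called outside its contract."""


class NormalizationError(HomeoscopeError):
    """Size-factor estimation is impossible (no gene nonzero in all samples)."""


class EstimationError(HomeoscopeError):
    """Dispersion estimation is impossible (no replication)."""
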