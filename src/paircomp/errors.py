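"""Exception hierarchy.

``DataError`` marks problems in the contest/covariate data themselves,
``ConfigurationError`` marks problems in how a run was configured (missing
columns, bad model strings, invalid prior scales), ``UsageError`` marks API
misuse (asking for a player the model never saw), and
``InitializationError`` marks a sampler that could not find a finite
starting point.
"""


class PairCompError(Exception):
    """Base class for all errors raised by paircomp."""


class DataError(PairCompError, ValueError):
    """The input data violate a documented invariant."""


class ConfigurationError(PairCompError, ValueError):
    """A run configuration (columns, model string, priors) is invalid."""


class UsageError(PairCompError, ValueError):
    """An operation was called in a way its contract forbids."""


class InitializationError(PairCompError, RuntimeError):
    """The sampler could not obtain a finite log-density at initialization."""
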