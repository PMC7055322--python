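"""Exception hierarchy for the trade-off pipeline.

All errors raised deliberately by this package derive from
:class:`TradeoffError`, so callers can distinguish domain failures from
programming bugs.
"""


class TradeoffError(Exception):
    """Base class for all deliberate errors raised by this package."""


class ConfigurationError(TradeoffError, ValueError):
    """A configuration object violates one of its invariants."""


class InsufficientDataError(TradeoffError, ValueError):
    """Too few observations to fit the requested model."""


class DegenerateDesignError(TradeoffError, ValueError):
    """The design has no usable variation (e.g. constant regressor)."""


class DomainError(TradeoffError, ValueError):
    """Input values outside the mathematical domain of an operation."""


class EncodingError(TradeoffError, ValueError):
    """A chromosome does not match the expected binary encoding."""


class ValidationError(TradeoffError, ValueError):
    """A dataset table failed schema or cross-reference validation."""


class BudgetExceededError(TradeoffError, RuntimeError):
    """An exhaustive enumeration would exceed the configured budget."""


class NoFeasibleSolutionError(TradeoffError, RuntimeError):
    """No landscape met the profit expectation within the search."""
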