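"""Exception hierarchy.

All errors raised by the package derive from :class:`BatchBalanceError`,
so callers (and the CLI) can catch one base class.
"""


class BatchBalanceError(Exception):
    """Base class for all batchbalance errors."""


class ValidationError(BatchBalanceError):
    """Input data violates an invariant (duplicate ids, bad values...)."""


class SchemaError(BatchBalanceError):
    """A column required by the covariate spec or options is absent."""


class ParseError(BatchBalanceError):
    """A cell could not be parsed as the declared covariate kind."""


class InfeasibleError(BatchBalanceError):
    """No allocation satisfying capacity and blocking constraints exists."""


class ConsistencyError(BatchBalanceError):
    """An allocation does not cover the sample table it is paired with."""
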