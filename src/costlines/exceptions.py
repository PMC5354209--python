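"""Exception hierarchy."""


class CostlinesError(Exception):
    """Base class for package errors."""


class ConfigurationError(CostlinesError, ValueError):
    """Invalid generator or pipeline configuration."""


class EmptyDataError(CostlinesError, ValueError):
    """No usable rows for the requested operation."""


class ConvergenceError(CostlinesError, RuntimeError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class DegenerateDataError(CostlinesError, ValueError):
    """Input is degenerate for the requested statistic (e.g. zero variance)."""
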