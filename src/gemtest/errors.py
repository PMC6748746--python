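"""Exception hierarchy.

Every error raised by the package derives from :class:`GemtestError` so
callers (and the test runner, which must distinguish assertion failures
from infrastructure errors) can catch package problems uniformly.
"""


class GemtestError(Exception):
    """Base class for all package errors."""


class ValidationError(GemtestError):
    """A model, reaction, or gene rule violates a structural invariant."""


class GeneRuleError(ValidationError):
    """A gene-reaction rule string could not be parsed."""


class OptimizationError(GemtestError):
    """An LP/MILP problem could not be set up or did not yield a usable status."""

    def __init__(self, message, status=None):
        super().__init__(message)
        self.status = status


class DiagnosticError(GemtestError):
    """A validation diagnostic could not be configured (e.g. contradictory bounds)."""


class DeltaError(GemtestError):
    """A strain-design delta is malformed or cannot be applied/resolved."""


class ProjectError(GemtestError):
    """Project configuration or layout problem."""


class IOFormatError(GemtestError):
    """Model file could not be read or written in the requested format."""
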