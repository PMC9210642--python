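"""Exception types raised across the pipeline.

Every precondition violation maps to a dedicated subclass so callers can
distinguish bad arguments from numerical failures.
"""


class SubpathnetError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SubpathnetError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientReplicatesError(InvalidArgumentError):
    """A contrast group has fewer than two samples."""


class NoEventsError(InvalidArgumentError):
    """A survival fit was requested on a cohort with zero observed events."""


class ConvergenceError(SubpathnetError):
    """An iterative fit exceeded its iteration budget.

    Carries the last iterate so callers can inspect how far the fit got.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class InvalidSeedsError(InvalidArgumentError):
    """No seed gene intersects the network (or a required seed set is empty)."""


class EmptyNetworkError(InvalidArgumentError):
    """Evidence filtering left no edges."""


class UncoveredSubpathwayError(InvalidArgumentError):
    """No member of a subpathway carries a propagation score."""


class AlignmentError(InvalidArgumentError):
    """Sample or feature identifiers do not line up between two inputs."""


class CollinearityError(InvalidArgumentError):
    """A covariate matrix is rank deficient.

    ``columns`` names the offending covariates.
    """

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = list(columns)


class InsufficientLinesError(InvalidArgumentError):
    """A median IC50 split left fewer than two cell lines in a group."""


class UndefinedCorrelationError(InvalidArgumentError):
    """Correlation requested against a constant vector."""
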