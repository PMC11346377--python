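"""Exception hierarchy shared across the package."""


class StreamnetError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(StreamnetError):
    """The edge table does not describe a valid dendritic network."""


class CycleError(TopologyError):
    """Following downstream pointers revisits an edge."""


class SchemaError(StreamnetError):
    """An input table violates the documented column/constraint schema.

    The message lists every violated constraint at once.
    """

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class FormatError(StreamnetError):
    """A dataset path does not match any recognized layout."""


class DimensionError(StreamnetError):
    """Matrix/vector dimensions do not conform."""


class RankError(StreamnetError):
    """A design (or whitened design) matrix is rank deficient."""


class SingularError(RankError):
    """Rank-deficient design detected during model fitting."""


class NotPDError(StreamnetError):
    """A covariance matrix is not positive definite after the jitter policy."""


class NotFittedError(StreamnetError):
    """A diagnostic or prediction was requested from an unconverged/absent fit."""


class ConvergenceWarning(UserWarning):
    """The optimizer hit its iteration cap; results may be inaccurate."""
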