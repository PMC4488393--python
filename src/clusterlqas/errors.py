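"""Exception types shared across the package."""


class ClusterLQASError(Exception):
    """Base class for all package-specific errors."""


class InvalidClusteringError(ClusterLQASError, ValueError):
    """Clustering parameters are incompatible with the coverage level.

    Raised when a requested (sigma, p) pair implies an intraclass
    correlation above 1, i.e. sigma^2 > p(1 - p).
    """


class DegenerateClusteringError(ClusterLQASError, ValueError):
    """Clustering is exactly zero where a positive value is required.

    The binomial-scaled model needs sigma > 0 to define its mixing index;
    with no clustering the plain binomial model should be used instead.
    """


class InfeasibleDesignError(ClusterLQASError, RuntimeError):
    """No design satisfying the risk constraints exists within search caps."""


class UndefinedEstimatorError(ClusterLQASError, ValueError):
    """The between-cluster variance estimator requires m >= 2."""


class SchemaError(ClusterLQASError, ValueError):
    """A survey-summary table does not conform to the expected schema."""
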