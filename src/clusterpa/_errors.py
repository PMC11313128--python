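"""Exception hierarchy used across the package."""


class ClusterPAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ClusterPAError, ValueError):
    """A simulation or pipeline configuration field is invalid.

    The message always names the offending field.
    """


class EstimationError(ClusterPAError, RuntimeError):
    """A variance-component or correlation estimate cannot be computed."""


class UndefinedICCError(EstimationError):
    """ICC is undefined (zero total variance)."""


class BoundaryICCError(EstimationError):
    """ICC sits on the boundary of [0, 1]; a two-sided logit interval
    does not exist and a one-sided bound should be used instead."""


class InsufficientDataError(EstimationError):
    """Too few schools or pupils to compute a correlation."""


class InfeasibleDesignError(ClusterPAError, ValueError):
    """No finite number of clusters can reach the requested power."""


class AllocationError(ClusterPAError, ValueError):
    """Cluster count is incompatible with the design geometry
    (e.g. not divisible by the number of stepped-wedge sequences)."""
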