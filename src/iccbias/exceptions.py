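"""Exception hierarchy for invalid designs and degenerate inputs."""


class IccError(ValueError):
    """Base class for all estimation and design errors raised by iccbias."""


class UnbalancedDesignError(IccError):
    """Clusters do not all share the same number of observations."""


class DegenerateDesignError(IccError):
    """Fewer than 2 clusters, or fewer than 2 observations per cluster."""


class NoVariationError(IccError):
    """All observations are (numerically) identical; the ICC is undefined."""


class InfiniteFError(IccError):
    """SSE = 0: the variance-ratio estimate diverges."""


class InsufficientDfError(IccError):
    """The design has too few within-cluster degrees of freedom."""


class VarianceUndefinedError(InsufficientDfError):
    """Var(F-hat) requires n(k-1) > 4; this design does not satisfy it."""
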