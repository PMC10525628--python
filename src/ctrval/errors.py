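"""Exception hierarchy for ctrval.

Every error raised by the library derives from :class:`CtrvalError`, so
callers (and the CLI) can catch one type at the boundary.
"""


class CtrvalError(Exception):
    """Base class for all ctrval errors."""


class EmptyMaskError(CtrvalError):
    """A mask with no foreground pixels was passed to a geometric routine."""


class InsufficientPairsError(CtrvalError):
    """Too few paired measurements for the requested statistic."""


class RelativeUndefinedError(CtrvalError):
    """Relative (percentage) differences requested but a pair mean is <= 0."""


class CaseMismatchError(CtrvalError):
    """Two rating matrices do not share the same case set."""


class IncompleteMeasurementsError(CtrvalError):
    """A case is missing one or more required measurements."""


class IncompleteReadersError(CtrvalError):
    """A reader did not label every case."""


class UnstableMetricError(CtrvalError):
    """A diagnostic metric was undefined in too many bootstrap resamples."""


class EmptySubgroupError(CtrvalError):
    """A subgroup filter selected no cases."""


class GoalUnachievableError(CtrvalError):
    """No finite sample size can satisfy the agreement design goal."""


class InfeasibleGeometryError(CtrvalError):
    """The requested thorax geometry cannot be rasterized at the image size."""


class InvalidConfusionError(CtrvalError):
    """A confusion matrix is not row-stochastic."""
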