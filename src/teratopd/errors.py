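"""Exception hierarchy shared by all analysis stages."""


class TeratopdError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TeratopdError, ValueError):
    """A record or argument violates a documented invariant."""


class EmptyInputError(TeratopdError, ValueError):
    """An operation received an empty collection where at least one item is required."""


class GridError(TeratopdError, ValueError):
    """Dose groups do not sit on an equally spaced log10 grid."""


class UnextendedSeriesError(TeratopdError, ValueError):
    """A dose series does not span 0% to 100% response, so the median-dose
    estimator is not applicable without the dummy-dose extension."""


class DegenerateDesignError(TeratopdError, ValueError):
    """The experimental design cannot support the requested estimate
    (e.g. a single dose group, or fewer than two comparison groups)."""
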