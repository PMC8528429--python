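"""Exception hierarchy shared across the pipeline stages."""


class CycleomicsError(ValueError):
    """Base class for all package-specific errors."""


class InvalidConfigError(CycleomicsError):
    """A configuration object violates its invariants."""


class InvalidInputError(CycleomicsError):
    """Input data violate a precondition (range, finiteness, membership)."""


class WrongScaleError(CycleomicsError):
    """An operation received a matrix on the wrong scale (counts vs log-CPM)."""


class InsufficientDesignError(CycleomicsError):
    """The time-course design cannot support the requested fit or test."""


class ConfoundingError(CycleomicsError):
    """Batch labels are collinear with protected design covariates."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class ZeroVarianceError(CycleomicsError):
    """A gene with zero variance cannot be z-scored."""

    def __init__(self, message, genes=()):
        super().__init__(message)
        self.genes = tuple(genes)


class DegenerateTraitError(CycleomicsError):
    """A clinical trait vector is constant and cannot be rank-correlated."""
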