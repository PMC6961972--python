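"""Exception hierarchy shared across the package."""


class NeuroasymError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NeuroasymError):
    """A table is missing required columns or has the wrong layout."""


class ValidationError(NeuroasymError):
    """Row-level invariant violations; message lists the offending rows."""


class UnknownRegionError(ValidationError):
    """A region label is not in the canonical list for its metric."""


class InsufficientSampleError(NeuroasymError):
    """Too few participants (or complete pairs) for the requested statistic."""


class DegenerateInputError(NeuroasymError):
    """Arithmetically undefined case, e.g. a zero bilateral mean or zero SD."""


class ModelError(NeuroasymError):
    """Latent-variable model specification or estimation failure."""


class ConvergenceError(ModelError):
    """The optimizer failed to reach the gradient-norm criterion."""
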