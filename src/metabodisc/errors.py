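"""Exception hierarchy shared by all pipeline stages."""


class MetabodiscError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(MetabodiscError):
    """An invalid configuration value; the message names the offending field."""


class InputError(MetabodiscError):
    """Malformed or incompatible input data."""


class ImputationError(MetabodiscError):
    """Half-minimum imputation impossible, e.g. a method with no observed value."""


class ScalingError(MetabodiscError):
    """Autoscaling impossible, e.g. a constant column."""


class ConvergenceError(MetabodiscError):
    """Iterative algorithm failed to converge within its iteration budget."""
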