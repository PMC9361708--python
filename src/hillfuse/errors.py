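"""Exception hierarchy for hillfuse."""


class HillfuseError(Exception):
    """Base class for all hillfuse errors."""


class InvalidRateError(HillfuseError):
    """Sampling rate incompatible with a requested filter or resampling step."""


class DataError(HillfuseError):
    """Input data violates a contract (non-finite samples, missing cycles, ...)."""


class ConfigError(HillfuseError):
    """Configuration value out of its admissible range or schema violation."""


class StabilityError(HillfuseError):
    """Recursive activation filter poles outside the unit circle."""


class AlignmentError(HillfuseError):
    """Two series that must share a sampling grid do not."""


class SchemaError(HillfuseError):
    """A delimited trial file is missing a mandatory column."""


class SolverError(HillfuseError):
    """Musculotendon equilibrium could not be established at some sample."""
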