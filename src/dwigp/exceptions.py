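"""Exception hierarchy for dwigp."""


class DwiGpError(Exception):
    """Base class for all dwigp errors."""


class InvalidInputError(DwiGpError, ValueError):
    """Malformed or out-of-contract input data."""


class InvalidHyperparameterError(DwiGpError, ValueError):
    """Hyperparameter outside its admissible range (e.g. non-positive scale)."""


class NumericalConditioningError(DwiGpError, RuntimeError):
    """A kernel matrix could not be factorised even after jitter."""


class FormatError(DwiGpError, ValueError):
    """A file on disk does not conform to the expected format."""


class InvalidComparisonError(DwiGpError, ValueError):
    """Two evidence results are not comparable (different data)."""
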