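"""Exception hierarchy shared across the package."""


class FractometryError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(FractometryError, ValueError):
    """Inputs are malformed: shape mismatch, wrong dtype family, bad layout."""


class DegenerateInputError(FractometryError, ValueError):
    """Input is structurally valid but carries no usable signal."""


class InsufficientDataError(FractometryError, ValueError):
    """Too few samples / bins to perform the requested fit or statistic."""


class ParameterError(FractometryError, ValueError):
    """A scalar parameter is outside its admissible range."""
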