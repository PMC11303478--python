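"""Exception hierarchy shared across the package."""


class GxesimError(Exception):
    """Base class for all package errors."""


class ParameterError(GxesimError, ValueError):
    """A simulation parameter violates its documented constraint."""


class ShapeError(GxesimError, ValueError):
    """Array dimensions are inconsistent with the requested operation."""


class DegenerateInputError(GxesimError, ValueError):
    """An input is structurally valid but carries no usable signal."""


class MatrixError(GxesimError, ValueError):
    """A matrix fails a structural requirement (symmetry, PSD-ness)."""


class NumericError(GxesimError, RuntimeError):
    """A linear solve or decomposition failed numerically."""
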