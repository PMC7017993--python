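"""Named error types raised across the pipeline stages."""


class FractalConnError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(FractalConnError):
    """An input file or table contained no data."""


class RaggedRowsError(FractalConnError):
    """A time-series table had rows of unequal length."""


class NonNumericCellError(FractalConnError):
    """A time-series table contained a non-numeric cell."""


class DeadRoiError(FractalConnError):
    """Zero-variance ROI columns reached a stage that cannot handle them."""


class AllRoisDeadError(FractalConnError):
    """Every ROI column had zero variance; the graph would be empty."""


class DegenerateSignalError(FractalConnError):
    """A signal has no curve length at any scale (e.g. constant series)."""


class GraphTooLargeError(FractalConnError):
    """The exact covering-number search is restricted to tiny graphs."""


class SchemaError(FractalConnError):
    """A results table is missing mapped columns or condition labels."""


class ConfigError(FractalConnError):
    """A run configuration is inconsistent or incomplete."""
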