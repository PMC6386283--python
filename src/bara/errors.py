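"""Exception hierarchy.

Every error raised by the package derives from :class:`BaraError`; each class
carries a distinct ``exit_code`` used by the command-line interface.
"""


class BaraError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(BaraError):
    """Malformed input data (non-finite values, duplicate labels, bad shape)."""

    exit_code = 3


class ParameterError(BaraError):
    """A parameter value outside its admissible range."""

    exit_code = 4


class ZeroVarianceError(BaraError):
    """The centered training matrix has no variance (all rows identical)."""

    exit_code = 5


class GeneSpaceError(BaraError):
    """Test-set gene identifiers do not match the fitted model's genes."""

    exit_code = 6


class ReferenceLookupError(BaraError):
    """A requested reference sample id is absent from the matrix."""

    exit_code = 7


class DegenerateBatchError(BaraError):
    """A batchwise statistic is degenerate (zero mean or zero variance)."""

    exit_code = 8
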