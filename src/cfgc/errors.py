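"""Exception hierarchy shared across the package."""


class CfgcError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(CfgcError):
    """A genomic interval is out of bounds or otherwise ill-formed."""


class ChromosomeNotFoundError(CfgcError, KeyError):
    """A chromosome name is absent from the genome."""


class BedParseError(CfgcError):
    """A BED record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class InputContractError(CfgcError):
    """An input file violates a structural precondition (e.g., unsorted BAM)."""


class GridMismatchError(CfgcError):
    """Two distributions or a model/distribution pair use different grids."""


class DegenerateDistributionError(CfgcError):
    """A fragment distribution has no usable counts."""


class DegenerateNormalizationError(CfgcError):
    """A composite-signal flank has zero coverage; normalization undefined."""


class EmptySignalError(CfgcError):
    """No region contributed to a composite signal."""


class ConfigError(CfgcError):
    """Invalid simulation or run configuration."""
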