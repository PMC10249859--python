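"""Exception hierarchy shared across the package."""


class NumtriskError(Exception):
    """Base class for all package errors."""


class FastaFormatError(NumtriskError):
    """Malformed FASTA input (duplicate ids, illegal characters, ...)."""


class TableFormatError(NumtriskError):
    """Malformed tabular input (gene table, truth table, hit table)."""


class SizingError(NumtriskError):
    """A requested sequence length cannot host the required features."""


class PlacementError(NumtriskError):
    """Insufficient scaffold space to place an insertion."""


class AlignmentSizeError(NumtriskError):
    """Sequence too long for the exact dynamic-programming aligner."""


class CalibrationError(NumtriskError):
    """Karlin-Altschul calibration failed to converge."""


class EstimationError(NumtriskError):
    """Too few usable data points for a statistical fit."""


class UndefinedDistanceError(NumtriskError):
    """A pairwise distance has no comparable alignment columns."""


class MitogenomeValidationError(NumtriskError):
    """A gene table contains names outside the canonical mitochondrial set."""


class ConfigError(NumtriskError):
    """Pipeline configuration violates the published schema."""
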