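"""Exception hierarchy shared across the pipeline."""


class MethanodivError(Exception):
    """Base class for all pipeline errors."""


class AlignmentLengthError(MethanodivError):
    """A record's sequence length differs from the alignment length."""


class DuplicateRecordError(MethanodivError):
    """Two records share the same id."""


class AlphabetError(MethanodivError):
    """A sequence character falls outside the declared alphabet."""


class LibraryTagError(MethanodivError):
    """A record lacks a library tag, or a tagging rule failed."""


class MatrixParseError(MethanodivError):
    """A distance-matrix file could not be parsed."""


class AsymmetryError(MatrixParseError):
    """A square distance matrix is asymmetric beyond tolerance."""


class IncomparablePairError(MethanodivError):
    """Two sequences share no comparable (non-gap, non-ambiguous) site."""


class SaturationError(MethanodivError):
    """An observed p-distance lies outside a correction model's domain."""


class ModelError(MethanodivError):
    """A distance model is incompatible with the alphabet or scale."""


class ClusteringError(MethanodivError):
    """Clustering input is invalid (NaN distances, missing ids)."""


class UndefinedStatisticError(MethanodivError):
    """A diversity statistic is undefined for the given abundances."""


class CalibrationError(MethanodivError):
    """Calibration input is degenerate or taxa cannot be paired."""


class LibshuffError(MethanodivError):
    """LIBSHUFF input is too small or malformed."""


class TreeError(MethanodivError):
    """Tree construction or manipulation failed."""


class SpecError(MethanodivError):
    """A synthetic-community specification is inconsistent or infeasible."""
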