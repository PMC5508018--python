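"""Exception hierarchy for mlsakit.

All package errors derive from :class:`MlsaError` so callers can catch one
base class; most also derive from the matching builtin (ValueError) so that
generic validation handling keeps working.
"""


class MlsaError(Exception):
    """Base class for all mlsakit errors."""


class EmptyInputError(MlsaError, ValueError):
    """An input file or collection contained no usable records."""


class AlignmentShapeError(MlsaError, ValueError):
    """Sequences in an alignment do not share a common length."""


class DuplicateIdError(MlsaError, ValueError):
    """A strain/record identifier occurred more than once."""


class MissingLocusError(MlsaError, KeyError):
    """A strain is absent from one of the loci being combined."""


class MatrixShapeError(MlsaError, ValueError):
    """A similarity/distance matrix is not square or lists mismatch."""


class MatrixRangeError(MlsaError, ValueError):
    """A matrix value lies outside the permitted [0, 100] range."""


class MatrixAsymmetryError(MlsaError, ValueError):
    """Mirrored cells of a square matrix disagree beyond tolerance."""


class InsufficientDataError(MlsaError, ValueError):
    """Too few sequences/points/strains for the requested statistic."""


class UndefinedContentError(MlsaError, ValueError):
    """A sequence has no unambiguous bases so base content is undefined."""


class UndefinedSimilarityError(MlsaError, ValueError):
    """A pair of sequences shares no comparable columns."""


class FrameError(MlsaError, ValueError):
    """A coding alignment is not a clean reading frame (length, stops)."""


class SaturationError(MlsaError, ValueError):
    """Divergence too high for the requested distance correction."""


class InvalidParameterError(MlsaError, ValueError):
    """A user-supplied parameter is outside its valid domain."""


class InvalidModelError(MlsaError, ValueError):
    """A calibration model violates its invariants (e.g. non-monotone)."""


class NonConvergenceError(MlsaError, RuntimeError):
    """All optimizer starts failed to converge."""


class SerializationError(MlsaError, ValueError):
    """An object cannot be written in the requested format."""
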