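"""Exception hierarchy for shapecomp."""


class ShapeCompError(Exception):
    """Base class for all shapecomp errors."""


class InvalidInputError(ShapeCompError, ValueError):
    """Malformed or insufficient input data (e.g. fewer than 3 points)."""


class AmbiguousInputError(ShapeCompError, ValueError):
    """Input admits more than one interpretation (e.g. multi-component mask)."""


class DegenerateShapeError(ShapeCompError, ValueError):
    """Shape has no usable geometry (zero area, all points coincident, ...)."""


class InsufficientPointsError(ShapeCompError, ValueError):
    """Too few contour points for the requested feature."""


class IncompatibleBankError(ShapeCompError, ValueError):
    """Descriptor vectors built with different descriptor banks."""


class DegenerateCorpusError(ShapeCompError, ValueError):
    """Corpus carries no descriptor variation at all."""


class UndefinedMetricError(ShapeCompError, ValueError):
    """Metric is undefined for the given inputs (e.g. IoU of two empty masks)."""


class GenerationFailureError(ShapeCompError, RuntimeError):
    """Synthetic shape generation exhausted its retry budget."""
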