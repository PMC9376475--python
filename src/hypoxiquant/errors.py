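"""Exception types shared across the pipeline."""


class HypoxiQuantError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HypoxiQuantError, ValueError):
    """Input violates a documented precondition."""


class SingularBasisError(HypoxiQuantError, ValueError):
    """Stain vectors are linearly dependent; deconvolution is impossible."""


class DegenerateTrainingError(HypoxiQuantError, ValueError):
    """Training data cannot support a classifier (e.g. a single class)."""


class InsufficientGroupingError(HypoxiQuantError, ValueError):
    """Too few grouping levels for a variance-component fit."""


class InvalidStructureError(HypoxiQuantError, ValueError):
    """Hierarchical ids do not form the required nesting."""


class UndefinedRecordError(HypoxiQuantError, ValueError):
    """A score is undefined (e.g. zero analyzed tissue area)."""


class PackingError(HypoxiQuantError, RuntimeError):
    """Synthetic nucleus placement failed after bounded retries."""
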