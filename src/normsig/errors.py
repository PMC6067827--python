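"""Exception hierarchy shared across the pipeline stages."""


class NormsigError(Exception):
    """Base class for all package-specific errors."""


class IdentifierError(NormsigError):
    """Duplicate or otherwise invalid gene/sample identifiers."""


class FormatError(NormsigError):
    """Malformed input file (non-numeric cell, missing value, bad header)."""


class AlignmentError(NormsigError):
    """Two objects that must share identifiers do not."""


class DesignError(NormsigError):
    """Invalid experimental design (wrong level counts, single-class split)."""


class DomainError(NormsigError):
    """Numeric value outside its mathematical domain."""


class ShapeError(NormsigError):
    """Dimension mismatch between congruent objects."""


class DegenerateSampleError(NormsigError):
    """A sample whose values admit no meaningful rank transform."""


class DegenerateInputError(NormsigError):
    """Input carries no usable variation (e.g. constant matrix)."""


class EmptyResultError(NormsigError):
    """An operation removed every gene or sample."""


class SpecError(NormsigError):
    """Infeasible synthetic-data specification."""


class RankError(NormsigError):
    """Requested factorization rank exceeds what the data supports."""
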