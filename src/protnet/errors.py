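"""Exception hierarchy for protnet."""


class ProtnetError(Exception):
    """Base class for all protnet errors."""


class StageError(ProtnetError):
    """An operation received an ExpressionMatrix at the wrong processing stage."""


class LabellingError(ProtnetError):
    """A sample or protein is missing a required label/annotation."""


class EmptyResultError(ProtnetError):
    """A filtering step removed everything."""


class DomainError(ProtnetError):
    """A value is outside the mathematical domain of an operation."""


class InsufficientDataError(ProtnetError):
    """Too few observations to carry out the operation."""


class NumericalRankError(ProtnetError):
    """A matrix involved in a computation is singular / rank deficient."""


class InsufficientSampleError(InsufficientDataError):
    """Sample size too small for the requested conditioning-set size."""


class InternalConsistencyError(ProtnetError):
    """An internal invariant was violated (indicates a bug upstream)."""


class ConvergenceError(ProtnetError):
    """An iterative fit failed to converge."""
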