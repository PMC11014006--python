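"""Exception hierarchy for the pipeline."""


class HfwaveError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(HfwaveError, ValueError):
    """A parameter violates its documented contract."""


class ResolutionError(HfwaveError, ValueError):
    """Sampling rate too low to resolve the requested morphology."""


class InsufficientDataError(HfwaveError, ValueError):
    """Too few beats / intervals / rows for the requested computation."""


class ContractViolationError(HfwaveError, ValueError):
    """An input object violates a structural invariant (e.g. non-monotone indices)."""


class NormalizationStateError(HfwaveError, ValueError):
    """A feature matrix is in the wrong normalization state for the operation."""
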