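"""Exception hierarchy for spindrop."""


class SpindropError(Exception):
    """Base class for all spindrop errors."""


class ParameterError(SpindropError, ValueError):
    """A physical parameter violates its validity constraints."""


class NoFlowError(SpindropError, RuntimeError):
    """An operation requires a flowing condition but the inlet velocity is zero."""


class DoesNotEmulsifyError(SpindropError, RuntimeError):
    """The initial state of a depletion run has no flow at all."""


class FitError(SpindropError, RuntimeError):
    """Exponential-law fitting failed (too few points, non-positive factors, ...)."""


class UntrainedAccelerationError(SpindropError, LookupError):
    """No fitted law exists at the requested centrifugal acceleration."""


class OutsideModelRangeError(SpindropError, RuntimeError):
    """No diameter in the admissible bracket satisfies the predictive law."""


class SaturatedAssayError(SpindropError, ValueError):
    """All droplets are positive; Poisson quantification is undefined."""
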