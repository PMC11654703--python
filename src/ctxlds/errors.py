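"""Package-specific exception types.

Kept deliberately flat: every error a caller might want to catch separately
gets its own class, all rooted at :class:`CtxldsError`.
"""


class CtxldsError(Exception):
    """Base class for all errors raised by ctxlds."""


class InvalidGridError(CtxldsError, ValueError):
    """Task grid construction failed (zero/duplicate strengths, bad shape)."""


class EigenPlanError(CtxldsError, ValueError):
    """Ground-truth eigenvalue plan is inconsistent (unpaired complex target,
    plan longer than the latent dimensionality, norms out of range)."""


class ShapeError(CtxldsError, ValueError):
    """Dimensionally inconsistent parameters or data."""


class SimulationOverflowError(CtxldsError, FloatingPointError):
    """Latent simulation produced non-finite values (unstable dynamics)."""


class DegenerateZScoreError(CtxldsError, ValueError):
    """A neuron had zero variance, so z-scoring is undefined."""


class DegenerateLoadingError(CtxldsError, ValueError):
    """Loading matrix is rank deficient; orthonormalization undefined."""


class ConfigError(CtxldsError, ValueError):
    """Invalid fitting or pipeline configuration."""


class DivergenceError(CtxldsError, RuntimeError):
    """Optimization produced NaN/Inf cost or gradients."""


class StabilityError(CtxldsError, ValueError):
    """Analysis requires a stable dynamics matrix (spectral radius < 1)."""


class BasisError(CtxldsError, ValueError):
    """Quantities expressed in incompatible latent bases were combined."""


class DegeneratePlaneError(CtxldsError, ValueError):
    """Coherence/|coherence| regression is rank deficient."""
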