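"""Exception hierarchy shared across the pipeline.

Validation problems (bad shapes, out-of-range thresholds, schema mismatches)
raise :class:`ValidationError`; numerical failures (non-convergence, divergent
indices) raise :class:`NumericalError`.  The CLI maps these onto exit codes
2 and 3 respectively.
"""


class CatechofluxError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CatechofluxError, ValueError):
    """Input data or configuration violates a documented contract."""


class NumericalError(CatechofluxError, ArithmeticError):
    """A computation failed numerically (degenerate geometry, no fit)."""


class UndefinedCorrelationError(ValidationError):
    """Correlation requested on constant input (zero variance)."""
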