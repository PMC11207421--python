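"""Exception hierarchy for the cwsilag package."""


class CwsilagError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(CwsilagError, ValueError):
    """A generator or pipeline configuration violates its constraints."""


class DegenerateSeriesError(CwsilagError, ValueError):
    """A series has zero variance where variation is required."""


class InsufficientOverlapError(CwsilagError, ValueError):
    """Shifted series overlap on too few samples to score a candidate lag."""


class InsufficientHistoryError(CwsilagError, ValueError):
    """A requested time shift reaches before the available padding."""


class FitFailureError(CwsilagError, RuntimeError):
    """Nonlinear least squares failed to converge from every start.

    Carries the best residual norm seen, for diagnostics.
    """

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class DegenerateBoundsError(CwsilagError, ValueError):
    """Empirical CWSI bounds (NWSB, NTB) coincide; the index is undefined."""


class AboveUpperLimitError(CwsilagError, ValueError):
    """Observed canopy warming exceeds the no-transpiration energy-balance limit."""
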