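"""Uniformly sampled scalar time series and the daily meteorology bundle.

Time is measured in minutes from local midnight.  Days are generated (and
ingested) with a pre-midnight padding margin so that shifted lookups
``x(t - tau)`` never wrap around the day boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CwsilagError, InvalidConfigError

__all__ = ["TimeSeries", "MeteoDay"]

_STEP_RTOL = 1e-9


def _validate_grid(t: np.ndarray) -> float:
    if t.ndim != 1 or t.size < 2:
        raise InvalidConfigError("time grid must be 1-D with at least 2 samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise CwsilagError("time grid must be strictly increasing")
    step = float(steps[0])
    if not np.allclose(steps, step, rtol=_STEP_RTOL, atol=1e-9):
        raise CwsilagError("time grid must have a constant step")
    return step


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    t : array of float
        Sample times in minutes from midnight, strictly increasing with a
        constant step (default field sampling is 2 min).
    v : array of float
        Sample values; the physical unit is carried in ``unit``.
    unit : str
        Unit tag, e.g. ``"degC"``, ``"%"``, ``"W/m^2"``, ``""`` (dimensionless).
    """

    t: np.ndarray
    v: np.ndarray
    unit: str = ""

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if t.shape != v.shape:
            raise CwsilagError(
                f"time and value arrays differ in shape: {t.shape} vs {v.shape}"
            )
        _validate_grid(t)
        if not np.all(np.isfinite(v)):
            raise CwsilagError("series contains non-finite values")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)

    @property
    def step(self) -> float:
        """Sampling step in minutes."""
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size

    def with_values(self, v: np.ndarray, unit: str | None = None) -> "TimeSeries":
        """Return a copy on the same grid with new values."""
        return TimeSeries(self.t, np.asarray(v, dtype=float),
                          self.unit if unit is None else unit)

    def window(self, start: float, end: float) -> "TimeSeries":
        """Restrict to samples with ``start <= t <= end`` (inclusive)."""
        mask = (self.t >= start) & (self.t <= end)
        if mask.sum() < 2:
            raise CwsilagError(f"window [{start}, {end}] holds fewer than 2 samples")
        return TimeSeries(self.t[mask], self.v[mask], self.unit)

    def value_at(self, time: float, tol: float | None = None) -> float:
        """Value at the grid sample nearest to ``time``.

        Raises if the nearest sample is farther than ``tol`` (default: one step).
        """
        tol = self.step if tol is None else tol
        i = int(np.argmin(np.abs(self.t - time)))
        if abs(self.t[i] - time) > tol + 1e-9:
            raise CwsilagError(f"no grid sample within {tol} min of t={time}")
        return float(self.v[i])

    def index_of(self, time: float) -> int:
        """Exact grid index of ``time`` (must lie on the grid)."""
        i = int(round((time - self.t[0]) / self.step))
        if i < 0 or i >= len(self) or abs(self.t[i] - time) > 1e-6:
            raise CwsilagError(f"t={time} is not on the sampling grid")
        return i


@dataclass(frozen=True)
class MeteoDay:
    """One day of micro-meteorology on a shared padded grid.

    All series share ``t``; the grid starts ``padding`` minutes before
    midnight (negative times) so lagged lookups have history.
    """

    t: np.ndarray
    ta: np.ndarray   # air temperature, degC
    rh: np.ndarray   # relative humidity, %
    rn: np.ndarray   # net radiation, W/m^2
    g: np.ndarray    # soil heat flux, W/m^2
    u: np.ndarray    # wind speed, m/s
    day: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        _validate_grid(t)
        object.__setattr__(self, "t", t)
        for name in ("ta", "rh", "rn", "g", "u"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise CwsilagError(f"{name} does not share the time grid")
            object.__setattr__(self, name, arr)
        if self.rh.min() < 5 - 1e-9 or self.rh.max() > 100 + 1e-9:
            raise CwsilagError("RH outside [5, 100]")
        if self.u.min() < -1e-12:
            raise CwsilagError("negative wind speed")

    @property
    def step(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def padding(self) -> float:
        """Minutes of pre-midnight history available."""
        return float(-self.t[0]) if self.t[0] < 0 else 0.0

    def series(self, name: str) -> TimeSeries:
        """One variable as a :class:`TimeSeries` (``ta, rh, rn, g, u``)."""
        units = {"ta": "degC", "rh": "%", "rn": "W/m^2", "g": "W/m^2", "u": "m/s"}
        if name not in units:
            raise KeyError(name)
        return TimeSeries(self.t, getattr(self, name), units[name])

    def daytime(self) -> "MeteoDay":
        """Restrict to the unpadded day (t >= 0)."""
        mask = self.t >= 0
        return replace(
            self, t=self.t[mask], ta=self.ta[mask], rh=self.rh[mask],
            rn=self.rn[mask], g=self.g[mask], u=self.u[mask],
        )
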