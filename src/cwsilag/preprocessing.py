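"""Savitzky-Golay smoothing and Z-score standardization.

Both are applied before lag estimation: smoothing removes 2-min sensor noise
while preserving the single diurnal peak, and Z-scoring makes the canopy and
air temperature series dimensionless and comparable for the estimators that
are not scale-invariant (notably grey relational analysis).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateSeriesError, InvalidConfigError
from .timeseries import TimeSeries

__all__ = ["savgol_smooth", "zscore"]


def savgol_smooth(series: TimeSeries, window: int = 31, polyorder: int = 3) -> TimeSeries:
    """Local least-squares polynomial smoothing on the series' own grid.

    Parameters
    ----------
    window : odd int
        Samples per local fit (default 31 = 62 min at 2-min sampling).
    polyorder : int
        Local polynomial degree, strictly less than ``window``.

    Edges are handled by evaluating the boundary polynomial fits
    (``mode="interp"``), so polynomials of degree <= ``polyorder`` are
    reproduced exactly over the whole grid.
    """
    if window % 2 == 0:
        raise InvalidConfigError("window must be odd")
    if polyorder >= window:
        raise InvalidConfigError("polyorder must be < window")
    if window > len(series):
        raise InvalidConfigError("window exceeds series length")
    smoothed = savgol_filter(series.v, window_length=window, polyorder=polyorder,
                             mode="interp")
    return series.with_values(smoothed)


def zscore(series: TimeSeries) -> TimeSeries:
    """Standardize to sample mean 0 and population SD 1 (ddof = 0).

    Raises :class:`DegenerateSeriesError` for a constant input instead of
    silently returning NaNs.
    """
    v = series.v
    sd = float(np.std(v))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSeriesError("cannot Z-score a constant series")
    return TimeSeries(series.t, (v - v.mean()) / sd, unit="")
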