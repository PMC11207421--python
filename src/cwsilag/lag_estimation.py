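"""Time-lag estimation between canopy and air temperature.

Three profile-based estimators, each scoring every candidate lag on the
sampling grid and returning the argmax:

* lagged Pearson cross-correlation,
* lagged mutual information (plug-in histogram estimator),
* grey time-lag relational analysis (pointwise distances normalized by the
  global extremes over all candidate shifts, resolution factor rho).

Sign convention: tau >= 0 means the canopy temperature lags the air
temperature, i.e. Tc(t) is paired with Ta(t - tau).  Shifted windows are
truncated (no wraparound, no padding); a candidate is only scored if the
overlap keeps at least half of the day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSeriesError, InsufficientOverlapError, InvalidConfigError
from .timeseries import TimeSeries

__all__ = [
    "LagProfile", "LagEstimate",
    "lag_cross_correlation", "mutual_information", "lag_mutual_information",
    "gray_relational_grade", "lag_gray_relational",
]

MIN_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class LagProfile:
    """Score versus candidate lag for one estimator."""

    method: str
    lags: np.ndarray       # minutes, strictly increasing, on the sampling grid
    scores: np.ndarray
    n_overlap: np.ndarray  # samples scored per candidate

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores)):
            raise DegenerateSeriesError("non-finite score in lag profile")

    @property
    def argmax_lag(self) -> float:
        """Lag of the maximal score; ties break to the smallest lag."""
        return float(self.lags[int(np.argmax(self.scores))])

    @property
    def at_boundary(self) -> bool:
        """True when the best score sits at the edge of the candidate grid —
        a sign the grid should be widened."""
        i = int(np.argmax(self.scores))
        return i == 0 or i == self.scores.size - 1


@dataclass(frozen=True)
class LagEstimate:
    """A single lag estimate: the profile argmax and its peak score."""

    tau: float       # minutes
    score: float
    method: str
    profile: LagProfile | None = None
    fits: tuple | None = None  # (tc_fit, ta_fit) for the peak-seeking method


def _candidate_shifts(tc: TimeSeries, ta: TimeSeries, max_lag: float) -> np.ndarray:
    if max_lag < 0:
        raise InvalidConfigError("max_lag must be non-negative")
    if len(tc) != len(ta) or not np.allclose(tc.t, ta.t):
        raise InvalidConfigError("tc and ta must share one sampling grid")
    n = len(tc)
    step = tc.step
    m_max = int(np.floor(max_lag / step + 1e-9))
    if n - m_max < MIN_OVERLAP_FRACTION * n:
        raise InsufficientOverlapError(
            f"max_lag={max_lag} min leaves less than "
            f"{MIN_OVERLAP_FRACTION:.0%} of the day overlapping")
    return np.arange(m_max + 1)


def lag_cross_correlation(tc: TimeSeries, ta: TimeSeries,
                          max_lag: float = 180.0) -> LagEstimate:
    """Lag at the maximum of the sliding Pearson correlation.

    For each candidate tau = m*step, the Pearson r between Tc(t) and
    Ta(t - tau) is computed over the truncated overlap.  The whole profile is
    evaluated in one pass from running sums and a single FFT-free
    cross-correlation, equivalent to a per-shift Pearson loop to rounding
    error.
    """
    shifts = _candidate_shifts(tc, ta, max_lag)
    x, y = tc.v, ta.v
    n = x.size
    step = tc.step

    # running sums: suffix over x (window x[m:]), prefix over y (window y[:n-m])
    sfx = np.cumsum(x[::-1])[::-1]
    sfx2 = np.cumsum((x ** 2)[::-1])[::-1]
    pre = np.cumsum(y)
    pre2 = np.cumsum(y ** 2)
    cross = np.correlate(x, y, mode="full")  # cross[n-1+m] = sum_i x[i+m]*y[i]

    L = (n - shifts).astype(float)
    sx = sfx[shifts]
    sx2 = sfx2[shifts]
    sy = pre[n - 1 - shifts]
    sy2 = pre2[n - 1 - shifts]
    sxy = cross[n - 1 + shifts]

    varx = sx2 - sx ** 2 / L
    vary = sy2 - sy ** 2 / L
    scale = max(np.max(sx2), np.max(sy2), 1.0)
    if np.any(varx <= 1e-12 * scale) or np.any(vary <= 1e-12 * scale):
        raise DegenerateSeriesError("zero-variance window in cross-correlation")
    r = (sxy - sx * sy / L) / np.sqrt(varx * vary)

    profile = LagProfile("cross_correlation", shifts * step, r, n - shifts)
    return LagEstimate(profile.argmax_lag, float(np.max(r)),
                       "cross_correlation", profile)


def _as_array(x) -> np.ndarray:
    return x.v if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)


def mutual_information(x, y, bins: int) -> float:
    """Plug-in mutual information (nats) from a 2-D equal-width histogram.

    Bins span each variable's own observed range, so the estimate is
    invariant to affine rescaling of either input.  The 0*log(0) terms
    contribute zero.
    """
    xa, ya = _as_array(x), _as_array(y)
    if xa.size != ya.size:
        raise InvalidConfigError("x and y must have equal length")
    if xa.size < 50:
        raise InvalidConfigError("need at least 50 samples for the MI estimate")
    if bins < 2:
        raise InvalidConfigError("bins must be >= 2")
    joint, _, _ = np.histogram2d(xa, ya, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def _sturges(n: int) -> int:
    return int(np.ceil(np.log2(n))) + 1


def lag_mutual_information(tc: TimeSeries, ta: TimeSeries,
                           max_lag: float = 180.0,
                           bins: int | None = None) -> LagEstimate:
    """Lag at the peak of the mutual information profile.

    ``bins=None`` uses the Sturges rule on each candidate's overlap length.
    Ties at the maximum break to the smallest lag.
    """
    shifts = _candidate_shifts(tc, ta, max_lag)
    x, y = tc.v, ta.v
    n = x.size
    step = tc.step

    scores = np.empty(shifts.size)
    for j, m in enumerate(shifts):
        L = n - m
        b = bins if bins is not None else _sturges(L)
        scores[j] = mutual_information(x[m:], y[:L], b)

    profile = LagProfile("mutual_information", shifts * step, scores, n - shifts)
    return LagEstimate(profile.argmax_lag, float(np.max(scores)),
                       "mutual_information", profile)


def gray_relational_grade(x, y, rho: float = 0.5,
                          delta_min: float | None = None,
                          delta_max: float | None = None):
    """Grey relational grade of y against reference x.

    zeta(k) = (d_min + rho*d_max) / (|x(k)-y(k)| + rho*d_max), grade = mean.
    ``delta_min``/``delta_max`` are the global extremes; when comparing a
    family of shifted sequences they must be taken over the whole family
    (the profile operation below supplies them).  If ``d_max`` is zero the
    sequences coincide and every coefficient is 1 by convention.

    Returns ``(grade, zeta)``.
    """
    xa, ya = _as_array(x), _as_array(y)
    if xa.size != ya.size:
        raise InvalidConfigError("x and y must have equal length")
    delta = np.abs(xa - ya)
    dmin = float(delta.min()) if delta_min is None else float(delta_min)
    dmax = float(delta.max()) if delta_max is None else float(delta_max)
    if dmax == 0.0:
        zeta = np.ones_like(delta)
    else:
        zeta = (dmin + rho * dmax) / (delta + rho * dmax)
    return float(zeta.mean()), zeta


def lag_gray_relational(tc: TimeSeries, ta: TimeSeries,
                        max_lag: float = 180.0,
                        rho: float = 0.5) -> LagEstimate:
    """Lag at the peak of the grey relational grade profile.

    The distance extremes d_min/d_max are taken jointly over all candidate
    shifts and positions (the double min/max of the defining formula), so
    grades at different lags share one normalization.  Inputs should be
    Z-scored first: the grade is not scale-invariant.
    """
    if rho <= 0:
        raise InvalidConfigError("rho must be positive")
    shifts = _candidate_shifts(tc, ta, max_lag)
    x, y = tc.v, ta.v
    n = x.size
    step = tc.step

    deltas = [np.abs(x[m:] - y[:n - m]) for m in shifts]
    dmin = min(float(d.min()) for d in deltas)
    dmax = max(float(d.max()) for d in deltas)

    scores = np.array([
        gray_relational_grade(x[m:], y[:n - m], rho, dmin, dmax)[0]
        for m in shifts
    ])
    profile = LagProfile("gray_relational", shifts * step, scores, n - shifts)
    return LagEstimate(profile.argmax_lag, float(np.max(scores)),
                       "gray_relational", profile)
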