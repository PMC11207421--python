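"""Crop Water Stress Index: energy-balance (theoretical) and baseline
(empirical) models, plus lag-corrected re-pairing of inputs.

Unit canon: temperatures degC, resistances s/m, pressures Pa internally;
the empirical-model boundary (VPD, VPG) works in kPa as the Tetens formula
emits it.  Gamma, gamma*, Delta are Pa/degC throughout.

The theoretical index follows the canopy energy balance: gamma* is evaluated
at the crop's minimum (potential-transpiration) canopy resistance ``rcp``,
while the actual canopy resistance ``rc`` is inverted from the observed
canopy-air temperature difference — the index is then

    CWSI = (gamma*(1 + rc/ra) - gamma_star) / (Delta + gamma*(1 + rc/ra)),

zero at rc = rcp and approaching one as the canopy stops transpiring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (AboveUpperLimitError, CwsilagError, DegenerateBoundsError,
                     DegenerateSeriesError, InvalidConfigError)
from .timeseries import MeteoDay, TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "RC_MIN_BY_STAGE", "TheoreticalParams", "EmpiricalBaseline", "LaggedPairs",
    "saturation_vapor_pressure", "vpd", "vpg", "psychrometric_gamma",
    "delta_slope", "aerodynamic_resistance", "fit_nwsb", "cwsi_empirical",
    "ctd_from_resistance", "canopy_resistance_inversion", "cwsi_theoretical",
    "apply_time_lag",
]

# minimum (potential) canopy resistance of winter wheat by growth period, s/m
RC_MIN_BY_STAGE = {
    "regreening-jointing": 13.01,
    "jointing-tasseling": 18.03,
    "tasseling-filling": 26.85,
}


# ---------------------------------------------------------------------------
# thermodynamic / aerodynamic components

def saturation_vapor_pressure(ta):
    """Tetens saturation vapor pressure es(T), kPa."""
    ta = np.asarray(ta, dtype=float)
    return 0.6108 * np.exp(17.27 * ta / (ta + 237.7))


def vpd(ta, rh):
    """Vapor pressure deficit, kPa: es(Ta) * (100 - RH)/100."""
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise InvalidConfigError("RH must lie in [0, 100] %")
    return saturation_vapor_pressure(ta) * (100.0 - rh) / 100.0


def vpg(ta, b):
    """Vapor pressure gradient es(Ta) - es(Ta + b), kPa.

    ``b`` is the intercept of the non-water-stressed baseline; the gradient
    places the upper (non-transpiring) bound of the empirical index.
    """
    return saturation_vapor_pressure(ta) - saturation_vapor_pressure(
        np.asarray(ta, dtype=float) + b)


def psychrometric_gamma(z_altitude):
    """Psychrometric coefficient at altitude Z (m), Pa/degC."""
    z = np.asarray(z_altitude, dtype=float)
    if np.any(z < 0):
        raise InvalidConfigError("altitude must be non-negative")
    return 0.665 * 101.3 * ((293.0 - 0.0065 * z) / 293.0) ** 5.26


def delta_slope(tc, ta):
    """Slope of the saturation vapor pressure curve, Pa/degC.

    Cubic in the canopy/air mean temperature T = (Tc + Ta)/2.  Outside the
    -10..50 degC calibration range a warning is logged and the polynomial is
    still evaluated.
    """
    t_mean = (np.asarray(tc, dtype=float) + np.asarray(ta, dtype=float)) / 2.0
    if np.any(t_mean < -10) or np.any(t_mean > 50):
        logger.warning("mean temperature outside -10..50 degC; "
                       "Delta extrapolated")
    return (45.03 + 3.014 * t_mean + 0.05345 * t_mean ** 2
            + 0.00224 * t_mean ** 3)


def aerodynamic_resistance(u, h, z=2.0):
    """Aerodynamic resistance ra, s/m.

    ra = 4.72 * [ln((z - d)/z0)]^2 / (1 + 0.54 u), with zero-plane
    displacement d = 0.63 h and roughness length z0 = 0.13 h.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise InvalidConfigError("wind speed must be non-negative")
    if h <= 0:
        raise InvalidConfigError("crop height h must be positive")
    d = 0.63 * h
    z0 = 0.13 * h
    if z <= d:
        raise InvalidConfigError(f"reference height z={z} must exceed d=0.63h={d}")
    if (z - d) / z0 <= 1:
        raise InvalidConfigError(f"(z-d)/z0 = {(z - d) / z0:.3f} must exceed 1")
    return 4.72 * np.log((z - d) / z0) ** 2 / (1.0 + 0.54 * u)


@dataclass(frozen=True)
class TheoreticalParams:
    """Site and crop constants of the energy-balance index."""

    altitude: float = 520.0     # m above sea level
    h: float = 0.7              # crop height, m
    z: float = 2.0              # reference height, m
    stage: str = "regreening-jointing"
    rho_air: float = 1.20       # air density, kg/m^3
    cp_air: float = 1013.0      # specific heat of air, J/kg/K

    def __post_init__(self):
        if self.h <= 0 or self.z <= 0.63 * self.h:
            raise InvalidConfigError("require h > 0 and z > 0.63 h")
        if self.stage not in RC_MIN_BY_STAGE:
            raise InvalidConfigError(
                f"unknown growth stage {self.stage!r}; "
                f"one of {sorted(RC_MIN_BY_STAGE)}")

    @property
    def rcp(self) -> float:
        """Minimum canopy resistance for the configured growth stage, s/m."""
        return RC_MIN_BY_STAGE[self.stage]


# ---------------------------------------------------------------------------
# empirical model

@dataclass(frozen=True)
class EmpiricalBaseline:
    """Non-water-stressed baseline CTD = a*VPD + b (degC/kPa, degC)."""

    a: float
    b: float
    fit_window: tuple[float, float] = (780.0, 900.0)
    r2: float = float("nan")
    n: int = 0


def fit_nwsb(ctd: TimeSeries, vpd_series: TimeSeries,
             window: tuple[float, float] = (780.0, 900.0)) -> EmpiricalBaseline:
    """OLS fit of the non-water-stressed baseline over a midday window.

    ``window`` defaults to 780-900 min (13:00-15:00), where the CTD-VPD
    linearity of a well-watered canopy is most distinct.
    """
    if not np.allclose(ctd.t, vpd_series.t):
        raise InvalidConfigError("ctd and vpd must share one grid")
    mask = (ctd.t >= window[0]) & (ctd.t <= window[1])
    n = int(mask.sum())
    if n < 2:
        raise InvalidConfigError(f"fewer than 2 samples in window {window}")
    x = vpd_series.v[mask]
    y = ctd.v[mask]
    if float(np.std(x)) == 0.0:
        raise DegenerateSeriesError("VPD has zero variance in the fit window")
    res = stats.linregress(x, y)
    return EmpiricalBaseline(float(res.slope), float(res.intercept),
                             (float(window[0]), float(window[1])),
                             float(res.rvalue ** 2), n)


def cwsi_empirical(tc, ta, rh, baseline: EmpiricalBaseline,
                   time=None, lag_applied: float = 0.0) -> pd.DataFrame:
    """Empirical (baseline) CWSI = (CTD - NWSB) / (NTB - NWSB).

    NWSB = a*VPD + b at the current deficit; NTB = a*VPG + b with the
    gradient evaluated through the baseline intercept.  The raw value is kept
    (it can legitimately leave [0, 1] in the field) next to a clamped
    companion.  Returns one row per sample with the bound components stored.
    """
    tc = np.atleast_1d(np.asarray(tc, dtype=float))
    ta = np.atleast_1d(np.asarray(ta, dtype=float))
    rh = np.atleast_1d(np.asarray(rh, dtype=float))
    ctd = tc - ta
    vpd_kpa = vpd(ta, rh)
    nwsb = baseline.a * vpd_kpa + baseline.b
    ntb = baseline.a * vpg(ta, baseline.b) + baseline.b
    denom = ntb - nwsb
    if np.any(np.abs(denom) < 1e-9):
        raise DegenerateBoundsError("NWSB and NTB coincide; CWSI undefined")
    raw = (ctd - nwsb) / denom
    return pd.DataFrame({
        "time": np.full(tc.shape, np.nan) if time is None else np.atleast_1d(time),
        "model": "empirical",
        "lag_applied": lag_applied,
        "cwsi_raw": raw,
        "cwsi_clamped": np.clip(raw, 0.0, 1.0),
        "ctd": ctd,
        "vpd": vpd_kpa,
        "nwsb": nwsb,
        "ntb": ntb,
    })


# ---------------------------------------------------------------------------
# theoretical model

def ctd_from_resistance(rc, rn, g, ra, vpd_pa, delta, gamma,
                        rho_air=1.20, cp_air=1013.0):
    """Forward energy balance: CTD implied by a given canopy resistance.

    With R = ra*(Rn - G)/(rho*cp) and gamma' = gamma*(1 + rc/ra):
    CTD = (R*gamma' - VPD) / (Delta + gamma').
    """
    rc = np.asarray(rc, dtype=float)
    R = np.asarray(ra, dtype=float) * (np.asarray(rn, dtype=float)
                                       - np.asarray(g, dtype=float)) / (rho_air * cp_air)
    gprime = np.asarray(gamma, dtype=float) * (1.0 + rc / np.asarray(ra, dtype=float))
    return (R * gprime - np.asarray(vpd_pa, dtype=float)) / (
        np.asarray(delta, dtype=float) + gprime)


def canopy_resistance_inversion(ctd, rn, g, ra, vpd_pa, delta, gamma,
                                rho_air=1.20, cp_air=1013.0):
    """Invert the canopy energy balance for the actual canopy resistance.

    Y = (CTD*Delta + VPD)/(R - CTD), rc = ra*(Y/gamma - 1); a negative
    solution is floored at 0 (flag ``"rc_floored"``).  CTD at or above the
    no-transpiration limit R raises :class:`AboveUpperLimitError`.

    Returns ``(rc, flag)`` with flag ``None`` when nothing was adjusted.
    """
    ctd = float(ctd)
    R = float(ra) * (float(rn) - float(g)) / (rho_air * cp_air)
    if R <= ctd:
        raise AboveUpperLimitError(
            f"CTD={ctd:.3f} degC at or above the energy-balance limit R={R:.3f}")
    Y = (ctd * float(delta) + float(vpd_pa)) / (R - ctd)
    rc = float(ra) * (Y / float(gamma) - 1.0)
    if rc < 0:
        return 0.0, "rc_floored"
    return rc, None


def cwsi_theoretical(tc, ta, rh, rn, g, u, params: TheoreticalParams,
                     time=None, lag_applied: float = 0.0) -> pd.DataFrame:
    """Energy-balance CWSI per timestamp.

    Computes gamma, Delta, ra, inverts the actual canopy resistance from
    CTD, and evaluates the index with gamma* at the growth stage's minimum
    canopy resistance.  CTD beyond the no-transpiration limit yields index 1
    with flag ``"above_upper_limit"``; a negative inverted resistance is
    floored at 0 with flag ``"rc_floored"``.
    """
    tc = np.atleast_1d(np.asarray(tc, dtype=float))
    ta = np.atleast_1d(np.asarray(ta, dtype=float))
    rh = np.atleast_1d(np.asarray(rh, dtype=float))
    rn = np.atleast_1d(np.asarray(rn, dtype=float))
    g = np.atleast_1d(np.asarray(g, dtype=float))
    u = np.atleast_1d(np.asarray(u, dtype=float))

    gamma = float(psychrometric_gamma(params.altitude))
    delta = delta_slope(tc, ta)
    ra = aerodynamic_resistance(u, params.h, params.z)
    vpd_pa = vpd(ta, rh) * 1000.0
    ctd = tc - ta
    R = ra * (rn - g) / (params.rho_air * params.cp_air)

    n = tc.size
    rc = np.empty(n)
    flags = np.array([None] * n, dtype=object)
    above = R <= ctd
    with np.errstate(divide="ignore", invalid="ignore"):
        Y = (ctd * delta + vpd_pa) / (R - ctd)
    rc_all = ra * (Y / gamma - 1.0)
    rc = np.where(rc_all < 0, 0.0, rc_all)
    flags[rc_all < 0] = "rc_floored"
    rc[above] = np.inf
    flags[above] = "above_upper_limit"

    gamma_star = gamma * (1.0 + params.rcp / ra)
    gprime = gamma * (1.0 + rc / ra)
    with np.errstate(invalid="ignore"):
        cwsi = (gprime - gamma_star) / (delta + gprime)
    cwsi[above] = 1.0

    return pd.DataFrame({
        "time": np.full(n, np.nan) if time is None else np.atleast_1d(time),
        "model": "theoretical",
        "lag_applied": lag_applied,
        "cwsi_raw": cwsi,
        "cwsi_clamped": np.clip(cwsi, 0.0, 1.0),
        "ctd": ctd,
        "vpd": vpd_pa / 1000.0,
        "gamma": gamma,
        "gamma_star": gamma_star,
        "delta": delta,
        "ra": ra,
        "rc": rc,
        "flag": flags,
    })


# ---------------------------------------------------------------------------
# lag correction

@dataclass(frozen=True)
class LaggedPairs:
    """Inputs re-paired for a lag-corrected CWSI evaluation.

    Canopy temperature stays at clock time t; air temperature and humidity
    are the values that actually drove it, tau minutes earlier (shifted
    jointly so VPD stays thermodynamically consistent); radiation, soil heat
    flux and wind stay contemporaneous.
    """

    t: np.ndarray
    tc: np.ndarray
    ta: np.ndarray
    rh: np.ndarray
    rn: np.ndarray
    g: np.ndarray
    u: np.ndarray
    lag_applied: float


def apply_time_lag(tc: TimeSeries, meteo: MeteoDay, tau: float) -> LaggedPairs:
    """Pair Tc(t) with (Ta, RH)(t - tau) and contemporaneous (Rn, G, u).

    ``tau`` must be a non-negative multiple of the grid step; history comes
    from the day's pre-midnight padding.  Samples whose shifted lookup would
    precede the padded grid are dropped with a logged count.
    """
    step = meteo.step
    if tau < 0:
        raise InvalidConfigError("tau must be non-negative")
    k = tau / step
    if abs(k - round(k)) > 1e-9:
        raise CwsilagError(f"tau={tau} min is not a multiple of the {step}-min grid")
    k = int(round(k))

    # indices of tc grid within meteo grid
    i0 = meteo.series("ta").index_of(float(tc.t[0]))
    idx = i0 + np.arange(len(tc))
    if idx[-1] >= meteo.t.size or not np.allclose(meteo.t[idx], tc.t):
        raise CwsilagError("tc grid is not a subset of the meteo grid")

    shifted = idx - k
    valid = shifted >= 0
    dropped = int((~valid).sum())
    if dropped:
        logger.info("apply_time_lag: dropped %d samples lacking %g min of history",
                    dropped, tau)
    if valid.sum() < 2:
        raise CwsilagError("insufficient history for the requested lag")
    return LaggedPairs(
        t=tc.t[valid],
        tc=tc.v[valid],
        ta=meteo.ta[shifted[valid]],
        rh=meteo.rh[shifted[valid]],
        rn=meteo.rn[idx[valid]],
        g=meteo.g[idx[valid]],
        u=meteo.u[idx[valid]],
        lag_applied=float(tau),
    )
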