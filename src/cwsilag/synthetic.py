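"""Synthetic diurnal micro-meteorology with a known canopy-response lag.

The generator emulates the drivers of a winter-wheat water-stress field trial:
a skewed single-peak diurnal air temperature, relative humidity moving against
it, half-sine daytime net radiation with proportional soil heat flux, an AR(1)
wind, a canopy temperature that follows air temperature with a configurable
delay and a stress-dependent canopy-air temperature difference (CTD), and
midday leaf gas-exchange observations (Pn, Tr, gs) that decline with stress
and drop sharply past a severe-stress threshold.

Every stochastic draw flows from an explicit :class:`numpy.random.Generator`;
regenerating with the same configuration and seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InsufficientHistoryError, InvalidConfigError
from .timeseries import MeteoDay, TimeSeries

__all__ = [
    "MeteoConfig", "StressScenario", "CanopyConfig", "PhotoConfig",
    "CampaignConfig", "PhotosynthesisObs", "SyntheticCampaign",
    "generate_meteo_day", "generate_canopy_temperature",
    "generate_photosynthesis", "generate_campaign", "default_scenarios",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class MeteoConfig:
    """Drivers of one synthetic day.

    Air temperature is a skewed Gaussian bump on a nocturnal baseline:
    width ``sigma_left`` before the peak, ``sigma_right`` after, so the
    afternoon cools more slowly than the morning warms — the asymmetry the
    peak-fitting equations are built for.
    """

    t_min: float = 8.0            # nocturnal baseline air temperature, degC
    t_max: float = 24.0           # peak air temperature, degC
    peak_time: float = 840.0      # Ta peak, minutes from midnight (14:00)
    sigma_left: float = 180.0     # pre-peak bump width, min
    sigma_right: float = 260.0    # post-peak bump width, min
    rh_max: float = 92.0          # RH at Ta = t_min, %
    rh_min: float = 35.0          # RH at Ta = t_max, %
    rn_peak: float = 650.0        # net radiation peak, W/m^2
    daylight: tuple[float, float] = (390.0, 1150.0)  # sunrise/sunset, min
    rn_night: float = 0.0         # nocturnal net radiation baseline, W/m^2
    cg: float = 0.1               # soil heat flux fraction of Rn
    u_mean: float = 1.5           # mean wind speed, m/s
    u_ar1_rho: float = 0.8        # AR(1) coefficient of wind perturbation
    u_ar1_sd: float = 0.3         # AR(1) innovation SD, m/s
    ta_noise_sd: float = 0.0      # additive Gaussian noise on Ta, degC
    step: float = 2.0             # sampling step, min
    padding: float = 240.0        # pre-midnight margin, min (>= max lag)

    def validate(self) -> None:
        if self.t_max <= self.t_min:
            raise InvalidConfigError("t_max must exceed t_min")
        if not (0 <= self.peak_time < 1440):
            raise InvalidConfigError("peak_time must lie within the day")
        if self.ta_noise_sd < 0 or self.u_ar1_sd < 0:
            raise InvalidConfigError("noise SDs must be non-negative")
        if self.sigma_left <= 0 or self.sigma_right <= 0:
            raise InvalidConfigError("bump widths must be positive")
        if self.step <= 0 or self.padding < 0:
            raise InvalidConfigError("step must be positive, padding non-negative")


@dataclass(frozen=True)
class StressScenario:
    """One irrigation treatment: dimensionless severity in [0, 1].

    ``fwc_pct`` (fraction of field water-holding capacity) is a label only;
    the generator consumes ``stress``.
    """

    label: str
    stress: float
    fwc_pct: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.stress <= 1.0):
            raise InvalidConfigError("stress must be in [0, 1]")


def default_scenarios() -> list[StressScenario]:
    """The four-treatment ladder: fully irrigated to severe stress."""
    return [
        StressScenario("T1", 0.00, 95.0),
        StressScenario("T2", 0.25, 80.0),
        StressScenario("T3", 0.55, 65.0),
        StressScenario("T4", 0.85, 50.0),
    ]


@dataclass(frozen=True)
class CanopyConfig:
    """Canopy temperature construction.

    ``baseline_a``/``baseline_b`` are the stress-free (Idso) CTD-vs-VPD line
    (degC/kPa, degC); ``dt_stress`` is the maximal additive CTD offset reached
    at stress 1.
    """

    baseline_a: float = -1.8
    baseline_b: float = 2.2
    dt_stress: float = 4.0
    noise_sd: float = 0.2     # white Gaussian noise on Tc, degC
    mode: str = "pure_delay"  # or "first_order"

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if self.mode not in ("pure_delay", "first_order"):
            raise InvalidConfigError(f"unknown canopy mode {self.mode!r}")


@dataclass(frozen=True)
class PhotoConfig:
    """Midday gas-exchange response to stress.

    Each parameter is ``baseline * (1 - rate*stress) * (1 - drop*[stress >= s_thr])``
    plus multiplicative noise, truncated at zero.  Default sensitivity ordering
    gs > Tr > Pn mirrors the field consensus that stomatal conductance reacts
    to soil drying first.
    """

    pn0: float = 25.0       # umol/m^2/s
    tr0: float = 6.0        # mmol/m^2/s
    gs0: float = 0.45       # mol/m^2/s
    rate_pn: float = 0.45
    rate_tr: float = 0.60
    rate_gs: float = 0.80
    s_thr: float = 0.70     # severe-stress threshold
    drop: float = 0.30      # fractional drop past the threshold
    noise_cv: float = 0.05  # coefficient of variation of the noise
    obs_time: float = 840.0  # minutes (14:00)

    def validate(self) -> None:
        for name in ("pn0", "tr0", "gs0"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        for name in ("rate_pn", "rate_tr", "rate_gs", "drop", "noise_cv"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PhotosynthesisObs:
    """One midday gas-exchange observation for a (day, treatment) cell."""

    pn: float
    tr: float
    gs: float
    obs_time: float
    scenario: StressScenario
    day: int


# ---------------------------------------------------------------------------
# generators

def generate_meteo_day(config: MeteoConfig, seed: int | np.random.Generator,
                       day: int = 0) -> MeteoDay:
    """Generate one day of micro-meteorology on a padded 2-min grid."""
    config.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    t = np.arange(-config.padding, 1440.0, config.step)

    # skewed single-peak diurnal air temperature
    amp = config.t_max - config.t_min
    sigma = np.where(t < config.peak_time, config.sigma_left, config.sigma_right)
    ta = config.t_min + amp * np.exp(-0.5 * ((t - config.peak_time) / sigma) ** 2)
    if config.ta_noise_sd > 0:
        ta = ta + rng.normal(0.0, config.ta_noise_sd, t.size)

    # RH affine-decreasing in Ta, clipped
    slope = (config.rh_max - config.rh_min) / amp
    rh = np.clip(config.rh_max - slope * (ta - config.t_min), 5.0, 100.0)

    # half-sine daytime net radiation; configurable nocturnal baseline
    t0, t1 = config.daylight
    rn = np.full_like(t, config.rn_night)
    day_mask = (t >= t0) & (t <= t1)
    rn[day_mask] = config.rn_night + config.rn_peak * np.sin(
        np.pi * (t[day_mask] - t0) / (t1 - t0))
    # padded pre-midnight samples correspond to the previous evening: keep the
    # same clock-time radiation so shifted pairings stay physically sensible
    pad_mask = t < 0
    tprev = t[pad_mask] + 1440.0
    prev_day = (tprev >= t0) & (tprev <= t1)
    rn[pad_mask] = np.where(
        prev_day,
        config.rn_night + config.rn_peak * np.sin(np.pi * (tprev - t0) / (t1 - t0)),
        config.rn_night)

    g = config.cg * rn

    # AR(1) wind perturbation, clipped at zero
    eps = rng.normal(0.0, config.u_ar1_sd, t.size)
    pert = np.empty(t.size)
    pert[0] = eps[0]
    for i in range(1, t.size):
        pert[i] = config.u_ar1_rho * pert[i - 1] + eps[i]
    u = np.clip(config.u_mean + pert, 0.0, None)

    return MeteoDay(t=t, ta=ta, rh=rh, rn=rn, g=g, u=u, day=day,
                    meta={"config": config})


def _saturation_vp(ta):
    # Tetens form shared with the CWSI module; duplicated here only to avoid
    # a circular import of a one-line formula
    return 0.6108 * np.exp(17.27 * np.asarray(ta) / (np.asarray(ta) + 237.7))


def _shift_lookup(t: np.ndarray, v: np.ndarray, tau: float) -> np.ndarray:
    """v(t - tau) on the grid t, using history (linear interp off-grid)."""
    step = t[1] - t[0]
    k = tau / step
    if abs(k - round(k)) < 1e-9:
        k = int(round(k))
        if k == 0:
            return v.copy()
        out = np.empty_like(v)
        out[k:] = v[:-k]
        out[:k] = np.nan  # caller guarantees tau <= padding so this is unused
        return out
    return np.interp(t - tau, t, v, left=np.nan, right=np.nan)


def generate_canopy_temperature(
    meteo: MeteoDay,
    tau: float,
    scenario: StressScenario,
    config: CanopyConfig = CanopyConfig(),
    seed: int | np.random.Generator = 0,
) -> TimeSeries:
    """Canopy temperature responding to air temperature with delay ``tau``.

    ``pure_delay`` mode (default):
        Tc(t) = Ta(t-tau) + [a*VPD(t-tau) + b] + stress*dt_stress + noise,
    with VPD computed from the jointly shifted Ta and RH, so the stress-free
    Idso line (a, b) is embedded exactly under lag-corrected pairing.

    ``first_order`` mode integrates the discrete relaxation
    Tc(t+step) = Tc(t) + (step/tau) * (Ta(t) + offset(t) - Tc(t));
    the recovered lag then only approximates ``tau``.

    Returned on the unpadded part of the grid (t >= 0).
    """
    config.validate()
    if tau < 0:
        raise InvalidConfigError("tau must be non-negative")
    if tau > meteo.padding + 1e-9:
        raise InsufficientHistoryError(
            f"tau={tau} min exceeds the padding margin ({meteo.padding} min)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    t = meteo.t
    if config.mode == "pure_delay":
        ta_s = _shift_lookup(t, meteo.ta, tau)
        rh_s = _shift_lookup(t, meteo.rh, tau)
        vpd_s = _saturation_vp(ta_s) * (100.0 - rh_s) / 100.0
        tc = (ta_s + config.baseline_a * vpd_s + config.baseline_b
              + scenario.stress * config.dt_stress)
    else:  # first_order
        offset = (config.baseline_a
                  * (_saturation_vp(meteo.ta) * (100.0 - meteo.rh) / 100.0)
                  + config.baseline_b + scenario.stress * config.dt_stress)
        target = meteo.ta + offset
        tc = np.empty_like(target)
        tc[0] = target[0]
        if tau == 0:
            tc = target.copy()
        else:
            alpha = meteo.step / tau
            for i in range(1, t.size):
                tc[i] = tc[i - 1] + alpha * (target[i - 1] - tc[i - 1])

    if config.noise_sd > 0:
        tc = tc + rng.normal(0.0, config.noise_sd, t.size)

    mask = t >= 0
    return TimeSeries(t[mask], tc[mask], "degC")


def generate_photosynthesis(
    scenarios: list[StressScenario],
    config: PhotoConfig = PhotoConfig(),
    seed: int | np.random.Generator = 0,
    day: int = 0,
) -> list[PhotosynthesisObs]:
    """Midday Pn/Tr/gs for each treatment; decline linear in stress with a
    discontinuous drop past the severe-stress threshold."""
    config.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    out = []
    for sc in scenarios:
        drop = 1.0 - config.drop * (sc.stress >= config.s_thr)
        vals = {}
        for name, base, rate in (("pn", config.pn0, config.rate_pn),
                                 ("tr", config.tr0, config.rate_tr),
                                 ("gs", config.gs0, config.rate_gs)):
            mean = base * (1.0 - rate * sc.stress) * drop
            noise = rng.normal(0.0, config.noise_cv * base) if config.noise_cv > 0 else 0.0
            vals[name] = max(mean + noise, 0.0)
        out.append(PhotosynthesisObs(vals["pn"], vals["tr"], vals["gs"],
                                     config.obs_time, sc, day))
    return out


# ---------------------------------------------------------------------------
# campaign

@dataclass(frozen=True)
class CampaignConfig:
    """A multi-day, multi-treatment campaign.

    ``true_lags`` maps treatment label to the imposed response delay
    (minutes); defaults span the magnitudes a field trial reports, with the
    severe treatment markedly shorter.  Day-to-day weather varies through
    Gaussian jitter of peak temperature and peak time.
    """

    n_days: int = 12
    scenarios: tuple[StressScenario, ...] = field(
        default_factory=lambda: tuple(default_scenarios()))
    true_lags: dict = field(default_factory=lambda: {
        "T1": 96.0, "T2": 92.0, "T3": 98.0, "T4": 76.0})
    meteo: MeteoConfig = MeteoConfig()
    canopy: CanopyConfig = CanopyConfig()
    photo: PhotoConfig = PhotoConfig()
    tmax_jitter_sd: float = 2.0   # day-to-day SD of peak air temperature, degC
    peak_jitter_sd: float = 30.0  # day-to-day SD of Ta peak time, min

    def validate(self) -> None:
        if self.n_days < 1:
            raise InvalidConfigError("n_days must be >= 1")
        for sc in self.scenarios:
            if sc.label not in self.true_lags:
                raise InvalidConfigError(f"no true lag for scenario {sc.label}")
            tau = self.true_lags[sc.label]
            if tau < 0 or tau > self.meteo.padding:
                raise InvalidConfigError(
                    f"true lag {tau} for {sc.label} outside [0, padding]")


@dataclass(frozen=True)
class SyntheticCampaign:
    """Generated campaign: ground truth for every downstream stage."""

    config: CampaignConfig
    days: list[MeteoDay]
    tc: dict          # (day, label) -> TimeSeries
    true_lag: dict    # label -> minutes
    photos: list[PhotosynthesisObs]
    seed: int

    def scenario(self, label: str) -> StressScenario:
        for sc in self.config.scenarios:
            if sc.label == label:
                return sc
        raise KeyError(label)


def generate_campaign(config: CampaignConfig = CampaignConfig(),
                      seed: int = 0) -> SyntheticCampaign:
    """Generate the full campaign from a single seed (bit-reproducible)."""
    config.validate()
    rng = np.random.default_rng(seed)

    days, tc, photos = [], {}, []
    for d in range(config.n_days):
        mc = config.meteo
        if config.tmax_jitter_sd > 0 or config.peak_jitter_sd > 0:
            mc = replace(
                mc,
                t_max=mc.t_max + rng.normal(0.0, config.tmax_jitter_sd),
                peak_time=float(np.clip(
                    mc.peak_time + rng.normal(0.0, config.peak_jitter_sd),
                    600.0, 1100.0)),
            )
            if mc.t_max <= mc.t_min + 2.0:
                mc = replace(mc, t_max=mc.t_min + 2.0 + abs(mc.t_max - mc.t_min - 2.0))
        meteo = generate_meteo_day(mc, rng, day=d)
        days.append(meteo)
        for sc in config.scenarios:
            tc[(d, sc.label)] = generate_canopy_temperature(
                meteo, config.true_lags[sc.label], sc, config.canopy, rng)
        photos.extend(generate_photosynthesis(
            list(config.scenarios), config.photo, rng, day=d))

    return SyntheticCampaign(config=config, days=days, tc=tc,
                             true_lag=dict(config.true_lags),
                             photos=photos, seed=seed)
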