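import numpy as np
import pytest

from cwsilag import (CanopyConfig, MeteoConfig, TimeSeries, default_scenarios,
                     generate_canopy_temperature, generate_meteo_day)


@pytest.fixture
def meteo_day():
    """One noise-free default day (only wind carries randomness)."""
    return generate_meteo_day(MeteoConfig(), seed=1)


@pytest.fixture
def well_watered():
    return default_scenarios()[0]


def make_delayed_pair(tau: float, seed: int = 1, noise_sd: float = 0.0):
    """(tc, ta) where tc is an exact (or noisy) delayed copy of ta.

    Uses a constant stress-free baseline (slope 0, intercept 0) so the canopy
    series is a pure shifted copy of the air series, the configuration under
    which every estimator should recover the lag exactly.
    """
    meteo = generate_meteo_day(MeteoConfig(), seed=seed)
    tc = generate_canopy_temperature(
        meteo, tau, default_scenarios()[0],
        CanopyConfig(baseline_a=0.0, baseline_b=0.0, noise_sd=noise_sd),
        seed=seed + 1000)
    ta = meteo.daytime().series("ta")
    return tc, ta


def delayed_arrays(n: int, shift: int, rng: np.random.Generator):
    """Raw arrays (tc, ta) on a shared 2-min grid with tc[i] = ta[i - shift].

    Built from one smooth random base so the equality is exact sample-wise.
    """
    base = np.cumsum(rng.normal(0, 1, n + shift))
    # mild smoothing keeps the series diurnal-like rather than white
    kernel = np.ones(9) / 9.0
    base = np.convolve(base, kernel, mode="same")
    tc = base[:n]
    ta = base[shift:shift + n]
    t = np.arange(n) * 2.0
    return TimeSeries(t, tc, "degC"), TimeSeries(t, ta, "degC")
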