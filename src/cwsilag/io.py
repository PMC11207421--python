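"""CSV ingestion/export and the campaign manifest.

Time columns are numeric minutes from midnight or ISO-8601 timestamps
(converted to minutes).  Grids are validated as uniform; gaps of at most two
steps are linearly interpolated with a logged count, larger gaps are an
error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CwsilagError
from .timeseries import MeteoDay, TimeSeries

logger = logging.getLogger(__name__)

__all__ = ["read_timeseries_csv", "read_meteo_csv", "write_timeseries_csv",
           "write_meteo_csv", "write_campaign"]

METEO_COLUMNS = ("Ta", "RH", "Rn", "G", "u")
MAX_GAP_STEPS = 2


def _times_to_minutes(col: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    ts = pd.to_datetime(col, errors="raise")
    midnight = ts.dt.normalize().iloc[0]
    return ((ts - midnight).dt.total_seconds() / 60.0).to_numpy()


def _regularize(t: np.ndarray, values: dict) -> tuple[np.ndarray, dict]:
    """Validate monotone time, infer step, fill gaps of <= 2 steps."""
    if np.any(np.diff(t) <= 0):
        raise CwsilagError("time column is not strictly increasing")
    steps = np.diff(t)
    step = float(np.median(steps))
    if step <= 0:
        raise CwsilagError("cannot infer a positive sampling step")
    ratio = steps / step
    if np.any(np.abs(ratio - np.round(ratio)) > 1e-6):
        raise CwsilagError("irregular sampling step beyond tolerance")
    if np.any(np.round(ratio) > MAX_GAP_STEPS + 1):
        raise CwsilagError(
            f"gap longer than {MAX_GAP_STEPS} steps; refusing to interpolate")
    full_t = np.arange(t[0], t[-1] + step / 2, step)
    n_filled = full_t.size - t.size
    if n_filled:
        logger.info("interpolated %d missing sample(s)", n_filled)
        values = {k: np.interp(full_t, t, v) for k, v in values.items()}
        return full_t, values
    return t, values


def read_timeseries_csv(path, time_col: str = "time_min",
                        value_col: str = "value", unit: str = "") -> TimeSeries:
    """Read a single-signal CSV with columns ``time_min,value``."""
    df = pd.read_csv(path)
    for col in (time_col, value_col):
        if col not in df.columns:
            raise CwsilagError(f"{path}: missing column {col!r}")
    t = _times_to_minutes(df[time_col])
    t, vals = _regularize(t, {"v": df[value_col].to_numpy(dtype=float)})
    return TimeSeries(t, vals["v"], unit)


def read_meteo_csv(path, column_map: dict | None = None, day: int = 0) -> MeteoDay:
    """Read a meteorology CSV with header ``time_min,Ta,RH,Rn,G,u``.

    ``column_map`` renames file columns to the canonical names, e.g.
    ``{"Rs": "Rn"}`` when the radiation column holds net radiation already.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "time_min" not in df.columns:
        raise CwsilagError(f"{path}: missing column 'time_min'")
    for col in METEO_COLUMNS:
        if col not in df.columns:
            raise CwsilagError(f"{path}: missing column {col!r}")
    t = _times_to_minutes(df["time_min"])
    t, vals = _regularize(
        t, {c: df[c].to_numpy(dtype=float) for c in METEO_COLUMNS})
    return MeteoDay(t=t, ta=vals["Ta"], rh=vals["RH"], rn=vals["Rn"],
                    g=vals["G"], u=vals["u"], day=day)


def write_timeseries_csv(series: TimeSeries, path) -> None:
    pd.DataFrame({"time_min": series.t, "value": series.v}).to_csv(
        path, index=False)


def write_meteo_csv(meteo: MeteoDay, path) -> None:
    pd.DataFrame({"time_min": meteo.t, "Ta": meteo.ta, "RH": meteo.rh,
                  "Rn": meteo.rn, "G": meteo.g, "u": meteo.u}).to_csv(
        path, index=False)


def write_campaign(campaign, outdir) -> Path:
    """Write a campaign: per-day meteo CSVs, per-plot Tc CSVs, gas-exchange
    observations, and a YAML manifest with scenarios, seed and true lags."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for d, meteo in enumerate(campaign.days):
        write_meteo_csv(meteo, outdir / f"meteo_day{d:02d}.csv")
    for (d, label), tc in campaign.tc.items():
        write_timeseries_csv(tc, outdir / f"tc_day{d:02d}_{label}.csv")
    pd.DataFrame([{
        "day": o.day, "label": o.scenario.label, "obs_time": o.obs_time,
        "Pn": o.pn, "Tr": o.tr, "gs": o.gs,
    } for o in campaign.photos]).to_csv(outdir / "photosynthesis.csv",
                                        index=False)
    manifest = {
        "seed": campaign.seed,
        "n_days": len(campaign.days),
        "true_lag_min": {k: float(v) for k, v in campaign.true_lag.items()},
        "scenarios": [{"label": sc.label, "stress": sc.stress,
                       "fwc_pct": sc.fwc_pct}
                      for sc in campaign.config.scenarios],
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir
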