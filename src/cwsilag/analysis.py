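"""Correlation of CWSI with midday gas exchange, before and after lag
correction.

For every cell (CWSI model x lag method x photosynthetic parameter) the CWSI
at the observation time is collected across treatments and days and the
parameter is regressed on it; the tables mirror the before/after heat maps a
field study reports.  The empirical baseline (NWSB) is always fitted on the
fully irrigated treatment only — it is by definition the non-water-stressed
line — pooled over days, under the same pairing (lag) as the cell being
evaluated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cwsi import (EmpiricalBaseline, TheoreticalParams, apply_time_lag,
                   cwsi_empirical, cwsi_theoretical, vpd)
from .errors import DegenerateSeriesError, InvalidConfigError
from .synthetic import SyntheticCampaign

logger = logging.getLogger(__name__)

__all__ = ["r_squared_linear", "fit_baseline_pooled", "cwsi_at_observations",
           "before_after_comparison", "delta_table", "plot_correlation_heatmap"]

PARAMETERS = ("pn", "tr", "gs")
LAG_METHODS = ("none", "peak_seeking", "cross_correlation",
               "mutual_information", "gray_relational")


def r_squared_linear(x, y):
    """Simple OLS of y on x; returns ``(r2, slope)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidConfigError("need >= 3 paired observations")
    if float(np.std(x)) == 0.0:
        raise DegenerateSeriesError("regressor has zero variance")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2), float(res.slope)


def _round_to_grid(tau: float, step: float) -> float:
    return round(tau / step) * step


def fit_baseline_pooled(campaign: SyntheticCampaign, tau_by_label: dict,
                        window=(780.0, 900.0)) -> EmpiricalBaseline:
    """NWSB from the least-stressed treatment, pooled over days.

    CTD and VPD are built from lag-corrected pairs at that treatment's tau,
    restricted to the midday fit window.
    """
    ref = min(campaign.config.scenarios, key=lambda s: s.stress)
    step = campaign.days[0].step
    tau = _round_to_grid(float(tau_by_label.get(ref.label, 0.0)), step)
    xs, ys = [], []
    for d, meteo in enumerate(campaign.days):
        pairs = apply_time_lag(campaign.tc[(d, ref.label)], meteo, tau)
        mask = (pairs.t >= window[0]) & (pairs.t <= window[1])
        xs.append(vpd(pairs.ta[mask], pairs.rh[mask]))
        ys.append(pairs.tc[mask] - pairs.ta[mask])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if float(np.std(x)) == 0.0:
        raise DegenerateSeriesError("pooled VPD has zero variance in the window")
    res = stats.linregress(x, y)
    return EmpiricalBaseline(float(res.slope), float(res.intercept),
                             tuple(window), float(res.rvalue ** 2), x.size)


def cwsi_at_observations(campaign: SyntheticCampaign, tau_by_label: dict,
                         model: str, params: TheoreticalParams | None = None,
                         baseline: EmpiricalBaseline | None = None,
                         obs_tol: float = 2.0) -> pd.DataFrame:
    """Raw CWSI at each gas-exchange observation (nearest grid sample).

    Returns one row per (day, treatment) with the photosynthetic parameters
    attached; observations lacking a grid sample within ``obs_tol`` minutes
    are skipped with a logged warning.
    """
    if model == "empirical" and baseline is None:
        baseline = fit_baseline_pooled(campaign, tau_by_label)
    if model == "theoretical" and params is None:
        params = TheoreticalParams()
    step = campaign.days[0].step

    rows = []
    for obs in campaign.photos:
        meteo = campaign.days[obs.day]
        label = obs.scenario.label
        tau = _round_to_grid(float(tau_by_label.get(label, 0.0)), step)
        pairs = apply_time_lag(campaign.tc[(obs.day, label)], meteo, tau)
        j = int(np.argmin(np.abs(pairs.t - obs.obs_time)))
        if abs(pairs.t[j] - obs.obs_time) > obs_tol + 1e-9:
            logger.warning("no CWSI sample within %.1f min of obs at t=%.0f "
                           "(day %d, %s); cell skipped",
                           obs_tol, obs.obs_time, obs.day, label)
            continue
        if model == "empirical":
            rec = cwsi_empirical(pairs.tc[j], pairs.ta[j], pairs.rh[j],
                                 baseline, time=pairs.t[j], lag_applied=tau)
        else:
            rec = cwsi_theoretical(pairs.tc[j], pairs.ta[j], pairs.rh[j],
                                   pairs.rn[j], pairs.g[j], pairs.u[j],
                                   params, time=pairs.t[j], lag_applied=tau)
        rows.append({"day": obs.day, "label": label, "stress": obs.scenario.stress,
                     "cwsi": float(rec["cwsi_raw"].iloc[0]),
                     "pn": obs.pn, "tr": obs.tr, "gs": obs.gs})
    return pd.DataFrame(rows)


def before_after_comparison(campaign: SyntheticCampaign,
                            lag_estimates: dict,
                            params: TheoreticalParams | None = None,
                            models=("empirical", "theoretical")) -> pd.DataFrame:
    """Tidy R^2 table over (model x lag method x parameter) cells.

    ``lag_estimates`` maps method name -> {treatment label -> tau minutes};
    the ``"none"`` method (tau = 0 everywhere, the uncorrected pairing) is
    always included.  Returns columns
    ``model, lag_method, parameter, r2, slope_sign, n``.
    """
    methods = {"none": {sc.label: 0.0 for sc in campaign.config.scenarios}}
    methods.update(lag_estimates)

    rows = []
    for model in models:
        for method, taus in methods.items():
            obs = cwsi_at_observations(campaign, taus, model, params=params)
            if len(obs) < 3:
                logger.warning("cell (%s, %s) has < 3 observations; skipped",
                               model, method)
                continue
            for p in PARAMETERS:
                r2, slope = r_squared_linear(obs["cwsi"], obs[p])
                rows.append({"model": model, "lag_method": method,
                             "parameter": p, "r2": r2,
                             "slope_sign": int(np.sign(slope)), "n": len(obs)})
    return pd.DataFrame(rows)


def delta_table(table: pd.DataFrame) -> pd.DataFrame:
    """Corrected-minus-uncorrected R^2 per (model, method, parameter)."""
    base = table[table.lag_method == "none"].set_index(["model", "parameter"])["r2"]
    rows = []
    for _, row in table[table.lag_method != "none"].iterrows():
        rows.append({
            "model": row.model, "lag_method": row.lag_method,
            "parameter": row.parameter,
            "delta_r2": row.r2 - base.loc[(row.model, row.parameter)],
        })
    return pd.DataFrame(rows)


def plot_correlation_heatmap(table: pd.DataFrame, path: str) -> None:
    """One heat-map panel per CWSI model: lag method x parameter R^2 cells."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    models = sorted(table.model.unique())
    fig, axes = plt.subplots(1, len(models), figsize=(5.2 * len(models), 3.6),
                             squeeze=False)
    for ax, model in zip(axes[0], models):
        sub = table[table.model == model].pivot(
            index="lag_method", columns="parameter", values="r2")
        sub = sub.reindex([m for m in LAG_METHODS if m in sub.index])
        im = ax.imshow(sub.to_numpy(), vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(sub.shape[1]), sub.columns)
        ax.set_yticks(range(sub.shape[0]), sub.index)
        for i in range(sub.shape[0]):
            for j in range(sub.shape[1]):
                ax.text(j, i, f"{sub.iloc[i, j]:.2f}", ha="center",
                        va="center", color="w", fontsize=8)
        ax.set_title(f"{model} CWSI vs gas exchange (R$^2$)")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
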