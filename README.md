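# cwsilag

Time-lag-aware crop water stress index (CWSI) analysis for winter-wheat
canopies, with a self-contained synthetic study generator.

## The scientific problem

Canopy temperature `Tc` responds to the atmosphere with inertia: on a clear
day it peaks tens of minutes after air temperature `Ta`. CWSI — the standard
thermal proxy for crop water stress — is built from the canopy-air
temperature difference `Tc − Ta`, so pairing the two series at the same clock
time mixes the canopy's state with the atmosphere's state from a different
physiological moment. That mispairing weakens the correlation between CWSI
and the gas-exchange parameters it is supposed to predict (net photosynthesis
`Pn`, transpiration `Tr`, stomatal conductance `gs`).

This package (1) estimates the `Tc`-vs-`Ta` time lag per day and treatment
with four independent estimators, (2) computes CWSI with and without lag
correction using both the empirical (Idso) and theoretical (Jackson
energy-balance) formulations, and (3) quantifies how much the correction
improves the CWSI / gas-exchange correlation on synthetic campaigns with
known ground truth.

## Models

**Empirical CWSI (Idso).** With the canopy-air temperature difference
`CTD = Tc − Ta`, the non-water-stressed baseline `NWSB = a·VPD + b` and the
non-transpiring bound `NTB = a·VPG + b` (where `VPG = es(Ta) − es(Ta + b)`),

```
CWSI = (CTD − NWSB) / (NTB − NWSB)
```

The baseline `(a, b)` is fitted by least squares on well-watered early
afternoon (13:00–15:00) observations.

**Theoretical CWSI (Jackson).** From the energy balance, with slope of the
saturation vapor pressure curve `Δ`, psychrometric constant `γ`, aerodynamic
resistance `ra` and canopy resistance `rc` (inverted from the observed CTD):

```
CWSI = (γ(1 + rc/ra) − γ*) / (Δ + γ(1 + rc/ra)),   γ* = γ(1 + rcp/ra)
```

where `rcp` is the stage-dependent minimum canopy resistance.

**Lag estimators.** Peak-seeking (difference of fitted diurnal peak times:
a Chesler-Cram-type exponential peak for `Tc`, an Edgeworth-Cramér series
peak for `Ta`), lagged Pearson cross-correlation, lagged mutual information,
and grey relational analysis. The three profile methods scan a 0–180 min
candidate grid in 2-min steps on truncated (non-circular) overlaps.

**Synthetic generator.** An asymmetric-Gaussian diurnal `Ta`, RH decreasing
affinely with `Ta`, half-sine net radiation, AR(1) wind, and a canopy series
constructed as a pure time-delayed transform of the air state with the Idso
baseline embedded exactly — so the true lag and the true baseline are known
to the tests and the acceptance script.

## Worked example

```python
import cwsilag as cw

camp = cw.generate_campaign(cw.CampaignConfig(n_days=6), seed=42)
per_day, averaged = cw.estimate_lags(
    camp, lag=cw.LagConfig(methods=("cross_correlation", "gray_relational")))
print("averaged lags (min):", averaged["cross_correlation"])

table = cw.before_after_comparison(
    camp, {"cross_correlation": averaged["cross_correlation"]},
    models=("empirical",))
print(table[table.parameter == "gs"][
    ["model", "lag_method", "parameter", "r2", "slope_sign", "n"]]
    .to_string(index=False))
```

Output:

```
averaged lags (min): {'T1': 96.0, 'T2': 92.0, 'T3': 98.0, 'T4': 76.0}
    model        lag_method parameter       r2  slope_sign  n
empirical              none        gs 0.656044          -1 24
empirical cross_correlation        gs 0.840627          -1 24
```

The estimated lags equal the campaign's true per-treatment lags (96, 92, 98,
76 min), and lag correction raises the CWSI-vs-`gs` R² from 0.66 to 0.84 with
the expected negative slope.

The same pipeline is available from the command line:

```bash
cwsilag all --seed 3 --n-days 6 --out out/
# writes config.yaml, campaign/, lag_estimates.csv, lag_averaged.csv,
# cwsi_observations.csv, correlation_table.csv, delta_table.csv, heatmap.png
```

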