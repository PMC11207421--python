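# Methods note

This note documents the models implemented in `cwsilag`, the assumptions
behind them, the default parameters and why they were chosen, what the
synthetic generator does and does not emulate, the numerical choices, and the
limitations of what the test suite demonstrates.

## 1. Problem setting

Canopy temperature `Tc` lags air temperature `Ta` on clear days because the
canopy-soil system has thermal inertia and stomatal regulation responds to
atmospheric demand with delay. CWSI is a function of the canopy-air
temperature difference `CTD = Tc − Ta`; pairing the two series at equal clock
time therefore evaluates the index against the wrong atmospheric state. The
package estimates the lag `τ` per day and treatment, re-pairs `Tc(t)` with
the air state at `t − τ`, and measures the effect on the CWSI vs
gas-exchange correlation.

Sign convention: positive `τ` means the canopy peaks after the air. The
lag-corrected pairing matches `Tc(t)` with `Ta(t − τ)` and `RH(t − τ)`;
radiation, soil heat flux and wind are taken contemporaneous with `Tc`, since
they drive the canopy energy balance at the moment of observation.

## 2. Models

### 2.1 Empirical (Idso) CWSI

```
NWSB = a·VPD + b                      (non-water-stressed baseline)
NTB  = a·VPG + b                      (non-transpiring bound)
VPG  = es(Ta) − es(Ta + b)
CWSI = (CTD − NWSB) / (NTB − NWSB)
```

`es` is the Tetens saturation vapor pressure
`es(T) = 0.6108·exp(17.27·T/(T + 237.7))` kPa. The baseline `(a, b)` is fitted by ordinary least squares on
the well-watered (least-stressed) treatment over the early-afternoon window
13:00–15:00, pooled over days, under the same lag pairing being evaluated.
Fitting the baseline under the cell's own pairing keeps the comparison
internally consistent: the uncorrected cell uses an uncorrected baseline.

`cwsi_raw` may leave [0, 1] on real data; a clamped copy is reported
alongside, and the raw value is used for correlation analysis so that
clamping cannot manufacture agreement.

### 2.2 Theoretical (energy-balance) CWSI

```
CWSI = (γ(1 + rc/ra) − γ*) / (Δ + γ(1 + rc/ra)),   γ* = γ(1 + rcp/ra)
γ(Z) = 0.665·101.3·((293 − 0.0065·Z)/293)^5.26            [Pa/°C]
Δ(T) = 45.03 + 3.014·T + 0.05345·T² + 0.00224·T³          [Pa/°C]
ra   = 4.72·[ln((z − d)/z0)]² / (1 + 0.54·u),  d = 0.63·h, z0 = 0.13·h
```

`Δ` is evaluated at the mean of canopy and air temperature. The canopy
resistance `rc` is inverted from the observed CTD:

```
R  = ra·(Rn − G)/(ρ·cp)          [°C]
Y  = (CTD·Δ + VPD_pa) / (R − CTD)
rc = ra·(Y/γ − 1)
```

Two guard rails: `R ≤ CTD` means the observed CTD exceeds the no-transpiration
upper bound, and the record is reported with `CWSI = 1` and an
`above_upper_limit` flag; a negative inverted `rc` (CTD below the theoretical
lower limit, e.g. advection) is floored at 0 with an `rc_floored` flag.
`rcp`, the minimum canopy resistance of a fully transpiring canopy, is
stage-dependent: 13.01 (regreening-jointing), 18.03 (jointing-tasseling),
26.85 (tasseling-filling) s/m.

The cubic `Δ` polynomial agrees with the analytic Tetens derivative to
within 3 % over 5–35 °C (verified in the tests); outside −10…50 °C the code
warns.

### 2.3 Lag estimators

All four estimators receive single-day daytime series on a uniform 2-min
grid. The three profile methods scan a candidate grid `τ ∈ {0, 2, …, 180}`
min, score `Tc(t)` against `Ta(t − τ)` on the truncated overlap (no
wraparound), require at least 50 % overlap, and break score ties toward the
smallest `τ`. An estimate at the grid boundary is flagged, since the true lag
may lie outside the scanned range.

- **Lagged Pearson cross-correlation** — implemented with running
  suffix/prefix sums and one FFT-free `np.correlate`, exactly equal (to
  1e-12, test-enforced) to a per-shift `scipy.stats.pearsonr` loop.
- **Lagged mutual information** — plug-in estimate on a 2-D histogram with
  Sturges' rule `⌈log₂ n⌉ + 1` bins per axis on the overlap, natural log.
- **Grey relational analysis** — coefficient
  `ζ(k) = (Δmin + ρ·Δmax)/(Δ(k) + ρ·Δmax)` with resolution `ρ = 0.5`; the
  grade is the mean of `ζ`. `Δmin`/`Δmax` are global over all candidate
  shifts jointly so grades are comparable across the profile. Exactly
  identical sequences (`Δmax = 0`) get grade 1 by convention. Inputs are
  standardized by the caller (the pipeline Z-scores first), not inside the
  function, so that exact delayed copies retain grade 1.
- **Peak-seeking** — fit a Chesler-Cram-type exponential peak ("CCE") to the
  smoothed `Tc` course and an Edgeworth-Cramér series peak ("ECS") to the
  smoothed `Ta` course; the lag is the difference of the fitted curves' peak
  times, each located by a dense 1-min argmax of the fitted curve (the
  composite peaks do not sit analytically at the location parameters; argmax
  ties break to the earlier time).

The CCE form is

```
y = y0 + A·( exp(−(x − xc1)²/(2w))
           + [1 − 0.5(1 − tanh(k2(x − xc2)))]·B·exp(−0.5·k3·(|x − xc3| + (x − xc3))) )
```

The switch is written with `tanh`; this family of peak equations is sometimes
written with a periodic `tan` in the gate, which is unbounded and makes the
fit ill-posed, so the implementation uses the bounded sigmoid and exposes
`use_literal_tan=True` only for comparison. The ECS form is a Gaussian
multiplied by a skew/kurtosis polynomial in `u = (x − xc)/w`:

```
1 + (a3/3!)·u(u² − 3) + (a4/4!)·(u⁴ − 6u³ + 3)
  + (10a3²/6!)·(u⁶ − 15u⁴ + 45u² − 15)
```

The `a4` term is implemented in this exact form (note the odd `−6u³` term,
which differs from the Hermite polynomial `H4`); it is kept as the package's
defining equation so that fits are reproducible against it.

**Peak-fit windowing.** For lag estimation both fits are restricted to ±90
min around each series' observed daily maximum (`window_half` argument;
`None` fits the full span). Rationale: both closed forms are only locally
adequate for a general asymmetric day course. Fitted over the full daytime
span each acquires a different global least-squares peak-time bias (about +8
min for CCE and +16 min for ECS on the generator's default shape), and the
biases do not cancel in the difference. Near the maximum both forms track
the curve closely; windowed fits localize the peaks nearly unbiasedly, and
the recovered lag is stable for window half-widths of 80–120 min. Fits use
`scipy.optimize.least_squares` (trf, `x_scale="jac"`) with six seeded,
jittered starts because the CCE surface is multi-modal.

### 2.4 Preprocessing

Savitzky-Golay smoothing (`scipy.signal.savgol_filter`, window 31 samples ≈
62 min, polynomial order 3, `mode="interp"`): wide enough to suppress
minute-scale noise without displacing an hour-scale peak, and order 3 passes
cubic trends exactly (test-enforced). Z-scoring uses population SD
(`ddof=0`) and raises on constant series rather than returning NaNs.

## 3. Synthetic generator

The generator is the package's ground-truth instrument: every campaign knows
its true per-treatment lag and its true embedded baseline.

What it emulates:

- an asymmetric-Gaussian diurnal `Ta` (default minimum 8 °C, maximum 24 °C
  at 14:00, morning sigma 180 min, afternoon sigma 260 min — mornings warm
  faster than afternoons cool);
- relative humidity affine-decreasing in `Ta` (92 % → 35 %), clipped to
  [5, 100] %;
- half-sine net radiation (peak 650 W/m², daylight 06:30–19:10), soil heat
  flux `G = 0.1·Rn`;
- AR(1) wind (mean 1.5 m/s, lag-1 correlation 0.8);
- canopy temperature in `pure_delay` mode:
  `Tc(t) = Ta(t − τ) + [a·VPD(t − τ) + b] + stress·ΔT + ε`, which embeds the
  Idso line exactly under the lag-corrected pairing (defaults `a = −1.8`
  °C/kPa, `b = 2.2` °C, stress elevation `ΔT = 4` °C, noise SD 0.2 °C); a
  `first_order` relaxation mode is available as a more physical alternative;
- four stress treatments (stress level 0 / 0.25 / 0.55 / 0.85);
- gas exchange observed at 14:00:
  `P = P0·(1 − k·stress)·(1 − 0.3·1[stress ≥ 0.7])`, with sensitivity
  ordered `gs > Tr > Pn` (k = 0.80 / 0.60 / 0.45) and 5 % multiplicative
  observation noise;
- day-to-day variation of the maximum temperature (SD 2 °C) and of the peak
  time (SD 30 min);
- a 4-hour pre-midnight padding so that lagged pairings near the start of
  the daytime window have history to draw on.

What it does **not** emulate: cloud passages and radiation intermittency,
advection, dew and rain, within-day stress dynamics, soil-moisture feedback
on the lag, sensor drift, view-angle or emissivity effects on radiometric
temperature, and non-stationary lags within a day (the true lag is one
number per treatment per campaign). Conclusions from the test suite are
therefore statements about internal consistency and method correctness on
this idealized ground truth — not field validation.

## 4. Analysis pipeline

Stages `simulate → preprocess → lag → cwsi → analyze`, runnable as a library
(`run_pipeline`) or CLI (`cwsilag all --seed … --out …`), with a lossless
YAML config round-trip and byte-identical deterministic reruns for a fixed
seed. Per-day lag estimates are averaged per treatment and method; CWSI is
evaluated at the 14:00 gas-exchange observation (±2 min tolerance); the
correlation table reports R², slope sign and n for every model × lag-method
× parameter cell, always including an uncorrected `none` row; the delta
table reports corrected-minus-uncorrected R².

## 5. Parameter defaults (summary)

| Parameter | Default | Why |
|---|---|---|
| sampling step | 2 min | typical IRT logging rate; sets the lag grid |
| candidate lag grid | 0–180 min, step 2 | generously covers hour-scale inertia |
| minimum overlap | 50 % | keeps per-shift scores statistically comparable |
| S-G window / order | 31 / 3 | ≈1 h window; passes cubics exactly |
| fit window half-width | 90 min | plateau of stable lag recovery (80–120) |
| MI bins | Sturges on overlap | standard plug-in default, n-adaptive |
| GRA ρ | 0.5 | conventional resolution coefficient |
| baseline window | 13:00–15:00 | near-steady early-afternoon conditions |
| altitude / height / z | 520 m / 0.7 m / 2 m | representative winter-wheat site |
| rcp by stage | 13.01 / 18.03 / 26.85 s/m | stage-resolved minimum resistance |
| ρ_air, cp | 1.20 kg/m³, 1013 J/(kg·K) | standard near-surface values |

## 6. Numerical choices

- `least_squares` (trf) with analytic-free Jacobians, `x_scale="jac"`,
  ftol 1e-10, xtol 1e-12, ≤5000 evaluations, 6 multistarts.
- Vectorized Pearson profile via running sums; equality with the naive loop
  is a frozen test at 1e-12.
- Dense 1-min argmax for fitted peaks; earliest-tie convention everywhere.
- All randomness flows from one `numpy.random.default_rng(seed)` passed down
  through the generator; reruns are byte-identical.
- Lag application requires `τ` to be a multiple of the sampling step; the
  analysis rounds averaged lags to the grid before pairing.

## 7. Limitations

- The peak-seeking estimator is the most fragile under noise (median error
  ≈13 min at `Tc` noise SD 0.3 °C versus 0–8 min for the profile methods on
  the same days); it is excluded from the noise-robustness checks and should
  be treated as a descriptive, not a precision, method.
- The empirical baseline is assumed linear in VPD and stable across days;
  the generator embeds exactly that, so baseline misspecification is not
  exercised.
- The theoretical model treats the canopy as a big-leaf with neutral
  atmospheric stability; stability corrections to `ra` are not implemented.
- MI and GRA scores are grid-resolution dependent; only the argmax location,
  not the score magnitude, is interpreted.
- Problem sizes in the tests (720-sample days, 12-day campaigns, 4
  treatments) are the package's own choices for fast, well-conditioned
  checks, not claims about required experimental designs.
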