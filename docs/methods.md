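# Methods

## Model and assumptions

`siftraits` retrieves electron transport rate (ETR), maximum carboxylation
rate (Vcmax) and stomatal conductance (gs) from canopy sun-induced
chlorophyll fluorescence (SIF) through a chain of closed-form relations.

**SIF to ETR.** In the lake model of PSII energy partitioning, absorbed
excitation is shared between photochemistry, constitutive thermal
dissipation (rate constant kD) and fluorescence (kF). With qL the fraction
of open reaction centers and ΦPSIImax the maximum photochemical yield,

    ETR = qL(PAR) · ΦPSIImax(1 + kDF) / ((1 − ΦPSIImax) ε) · SIF,
    kDF = kD/kF,   ε ≈ NIRv/FPAR.

ε is the canopy escape probability: only a fraction of emitted
fluorescence photons reach the sensor, approximated by the ratio of the
near-infrared reflectance of vegetation to the fraction of absorbed PAR.
The relation is *nonlinear in PAR* through qL even though it is linear in
SIF at fixed light: this is what distinguishes the chain from a pooled
SIF–Vcmax regression. With the defaults ΦPSIImax = 0.83 and kDF = 19 the
mechanistic gain ΦPSIImax(1+kDF)/(1−ΦPSIImax) is 97.647059.

Assumptions: an unstressed C3 canopy (no photoinhibition, so ΦPSIImax and
kDF are treated as constants), and that a single qL(PAR) law holds across
the season. No NPQ dynamics and no radiative transfer are modeled.

**qL light response.** qL declines with PAR as closed centers accumulate;
the package fits qL = a·exp(b·PAR) (a > 0, b ≤ 0) by nonlinear least
squares on the original scale, initialized from the log-linear fit of
ln qL on PAR. Fitting on the original scale avoids the error reweighting
a log transform introduces; the log-linear fit is only a starting point,
and the optimizer's residual sum of squares is asserted never to exceed
it. R² is reported as 1 − SSres/SStot on the original scale. Predictions
are clamped into (0, 1] (qL is a fraction); clamping is logged.

**ETR to Vcmax.** Evolutionary optimality assumes leaves coordinate the
Rubisco-limited and electron-transport-limited capacities to be
co-limiting under typical conditions, Ac = Aj. With Ac = Vcmax·mc and
Aj = (ETR/4)·m, where

    m  = (Ci − Γ*) / (Ci + 2Γ*),      mc = (Ci − Γ*) / (Ci + Km),

this solves to **Vcmax = ETR·m/(4·mc)**. The factor 4 (four electrons per
carboxylation in Aj) is carried through from Aj = (ETR/4)·m; dropping it
would place default-parameter retrievals near 2.7·ETR, far outside
plausible crop Vcmax magnitudes.

**ETR to gs.** Net assimilation follows from the electron-use efficiency
of C3 photosynthesis, A = (ETR/4)·m, and Fick's law A = gs·(Ca − Ci)/1.6,
giving **gs = 0.4·m·ETR/(Ca − Ci)**. The constant 1.6 is the water-to-CO2
diffusivity ratio (`diffusivity_ratio`, configurable); the implied A is
recoverable as gs·(Ca−Ci)/1.6 and equals (ETR/4)·m exactly, an identity
the tests assert.

## Parameters, units, defaults

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| `phi_psii_max` | max PSII photochemical yield | – | 0.83 | typical unstressed C3 value |
| `k_df` | kD/kF rate-constant ratio | – | 19 | standard lake-model constant |
| `ci` | intercellular CO2 | μmol mol⁻¹ | 280 | Ci/Ca ≈ 0.7 C3 operating point |
| `ca` | ambient CO2 | μmol mol⁻¹ | 400 | present-day ambient |
| `gamma_star` | CO2 compensation point | μmol mol⁻¹ | 42.75 | 25 °C literature value |
| `km` | effective Rubisco Km | μmol mol⁻¹ | 711 | 25 °C literature value |
| `diffusivity_ratio` | H2O:CO2 diffusivity | – | 1.6 | Fick's law constant |
| `sif_scale` | SIF unit calibration | – | 1.0 | use radiance literally |

CO2 quantities are treated as mole fractions; only differences and ratios
enter the chain, so partial pressures work too if used consistently. SIF
(mW m⁻² nm⁻¹ sr⁻¹) enters ETR (μmol m⁻² s⁻¹) with the radiometric/photon
conversion absorbed into the proportionality; `sif_scale` exposes an
explicit calibration factor for physically calibrated use. No temperature
response of Γ*, Km or ΦPSIImax is applied; retrievals at temperatures far
from 25 °C inherit that bias. Time is (year, day-of-year); an optional
fractional-hour column is carried through untouched, and whether the
series is instantaneous-midday or daily-mean is the user's choice — the
chain is applied per record either way.

## Sensitivity analysis

Both ΦPSIImax and kDF enter ETR only through the global gain
C = Φ(1+kDF)/(1−Φ), so a relative perturbation rescales every retrieved
ETR, Vcmax and gs by one closed-form factor: +10 % kDF by
(1+1.1·19)/(1+19) = 1.095, +10 % ΦPSIImax by
(0.913·0.17)/(0.83·0.087) ≈ 2.1494. The point elasticities of ln ETR are
1/(1−Φ) = 5.882 for ΦPSIImax and kDF/(1+kDF) = 0.95 for kDF: the chain is
roughly six times as sensitive to ΦPSIImax in relative terms, so that
parameter must be set accurately. `sensitivity_analysis` runs the
retrieval at ±10 % one-at-a-time (both signs, other parameters held) and
reports relative rather than absolute changes, which makes the result
independent of the particular series; `analytic_elasticities` provides
the closed-form cross-check, verified against finite differences.

## Synthetic data generator

`simulate_season` generates a season by *inverting the retrieval chain*:
a smooth log-normal-shaped true Vcmax trajectory (default peak
130 μmol m⁻² s⁻¹ early in a 120-day season, declining toward harvest,
shape (mode, sigma) = (0.25, 0.8) on normalized season time) is mapped to
ETR* = 4·Vcmax*·mc/m and gs*, PAR follows a smooth 325–500 W m⁻² arc,
NIRv and FPAR follow double-logistic green-up/senescence curves, and the
noise-free SIF is solved from the ETR equation. Observation noise is
multiplicative mean-one lognormal (SIF and reflectance indices are
positive), parameterized by a coefficient of variation — default 5 % on
SIF, 0 on the indices, seed 42. `generate_ql_pairs` produces 40 (qL, PAR)
pairs on an even 0–2000 W m⁻² grid with optional additive Gaussian noise.

Because the generator is the exact inverse of the retrieval, zero-noise
simulations are recovered to machine precision — that validates the
algebra and the plumbing, not the physics. Passing tests therefore show
self-consistency and noise robustness of the chain; they cannot show that
the lake model, the qL law, or Ac = Aj hold for a given real canopy, nor
do the noise CVs claim to describe any particular spectrometer. Real data
additionally contain structure the generator omits: diurnal cycles,
weather-driven PAR variability, stress episodes violating constant
ΦPSIImax, and correlated (not independent lognormal) observation errors.

## Numerical choices

- Degenerate records (ε ≤ 0 via NIRv = 0 or FPAR out of (0, 1], negative
  SIF) are skipped with a logged count, never propagated as NaN; an
  all-skipped series is an error. Missing CSV fields are dropped-and-
  logged at read time, not imputed.
- The qL fit caps the optimizer at 10 000 function evaluations; a fitted
  b > 0 (qL increasing with light) is rejected as outside the model
  family. R² is clipped at 0 when the fit is worse than the mean, with a
  log note.
- Negative linear-baseline predictions are floored at 0 (Vcmax is
  non-negative), logged.
- R² in `evaluate` is the squared Pearson correlation, reported together
  with the OLS slope/intercept of predictions on observations; for simple
  OLS with intercept this coincides with regression R². A constant
  prediction vector yields R² = 0 by convention.
- "Accuracy improvement" is 100·(MAE_baseline − MAE_model)/MAE_baseline,
  defined on MAE (not RMSE).
- Write precision is 10 significant digits, making CSV round trips exact
  to 1e-9 relative.
- Seasons longer than a calendar year wrap (year increments, DOY resets),
  keeping (year, DOY) keys unique and ordered.

## Problem sizes

The shipped tests and the acceptance script run on 40–120-day synthetic
seasons, 40-pair qL fixtures, and a single 1000-day series for the
asymptotic-unbiasedness check — sizes at which every property of the
closed-form chain is already exercised; the whole suite completes in a
few seconds on one core.

## Known limitations

- The SIF→ETR proportionality hides the radiometric-to-photon-flux
  conversion; absolute trait magnitudes are only as good as `sif_scale`
  and the assumed constants.
- Ci is fixed, not solved jointly with gs; under stomatal closure the
  fixed Ci/Ca assumption biases both Vcmax and gs.
- One qL(PAR) law per run: canopy-depth and stress dependence of qL are
  not modeled.
- No uncertainty propagation beyond the one-at-a-time analysis; no global
  (variance-based) sensitivity measures.
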