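# siftraits

Semimechanistic retrieval of photosynthetic functional traits — the maximum
carboxylation rate of Rubisco (V<sub>cmax</sub>) and stomatal conductance
(g<sub>s</sub>) — from canopy sun-induced chlorophyll fluorescence (SIF)
time series of a C3 crop.

SIF is a radiance signal (mW m⁻² nm⁻¹ sr⁻¹) re-emitted by chlorophyll
during photosynthesis and is now routinely measured by tower spectrometers
and satellites. `siftraits` is for crop phenomics and ecophysiology users
who have such a SIF/reflectance time series and want mechanistically
grounded trait estimates instead of a site-specific empirical regression.

## The model

The chain has three stages, all per timestamp:

1. **SIF → ETR.** In the "lake" model of PSII energy partitioning, the
   electron transport rate is proportional to SIF:

   ETR = q<sub>L</sub>(PAR) · Φ<sub>PSIImax</sub>(1+k<sub>DF</sub>) / [(1−Φ<sub>PSIImax</sub>) ε] · SIF

   where q<sub>L</sub>(PAR) = a·e<sup>b·PAR</sup> is the fraction of open
   PSII reaction centers (fitted to (q<sub>L</sub>, PAR) pairs),
   Φ<sub>PSIImax</sub> = 0.83 is the maximum PSII photochemical yield,
   k<sub>DF</sub> = k<sub>D</sub>/k<sub>F</sub> = 19 the
   thermal-dissipation/fluorescence rate-constant ratio, and
   ε ≈ NIRv/FPAR the canopy escape probability of fluorescence photons.

2. **ETR → V<sub>cmax</sub>.** Evolutionary optimality coordinates
   Rubisco-limited and electron-transport-limited assimilation
   (A<sub>c</sub> = A<sub>j</sub>), giving
   V<sub>cmax</sub> = ETR · m/(4 m<sub>c</sub>) with
   m = (C<sub>i</sub>−Γ*)/(C<sub>i</sub>+2Γ*),
   m<sub>c</sub> = (C<sub>i</sub>−Γ*)/(C<sub>i</sub>+K<sub>m</sub>).

3. **ETR → g<sub>s</sub>.** Electron-use efficiency gives net assimilation
   A = (ETR/4)·m; Fick's law A = g<sub>s</sub>(C<sub>a</sub>−C<sub>i</sub>)/1.6
   then yields g<sub>s</sub> = 0.4·m·ETR/(C<sub>a</sub>−C<sub>i</sub>).

The package also ships the linear SIF→V<sub>cmax</sub> baseline the
mechanism is compared against, the accuracy indices (R², MAE, RMSE, OLS
slope, MAE-improvement %), a ±10 % one-at-a-time sensitivity analysis of
Φ<sub>PSIImax</sub> and k<sub>DF</sub> with analytic elasticity
cross-checks, and a forward simulator that generates synthetic seasons
with known trait truth so the whole chain is testable without field data.

## Worked example

Simulate a 120-day season with 5 % SIF noise, fit the q<sub>L</sub>–PAR
law from 40 synthetic pairs, retrieve the traits, and score them against
the generating truth:

```sh
siftraits simulate --seed 42 --out sim
siftraits fit-ql --input sim/ql_pairs.csv --out ql.yaml
# prints: a=0.893788 b=-0.000986624 r2=0.9948 n=40
siftraits estimate --input sim/season.csv \
    --ql-a 0.893788 --ql-b -0.000986624 --out traits.csv
siftraits evaluate --obs-file sim/truth.csv --obs-col vcmax \
    --pred-file traits.csv --pred-col vcmax --out metrics.csv
# prints: r2=0.9932 mae=2.301 rmse=3.092 slope=1.0119 intercept=-0.9426 n=120
```

The fitted exponential recovers the generating coefficients (a = 0.9,
b = −0.001) within about 1 %, and the retrieved V<sub>cmax</sub> tracks
the true seasonal trajectory with R² = 0.993, an OLS slope of 1.01 (no
systematic bias) and an MAE of 2.3 μmol m⁻² s⁻¹ against a seasonal peak
of 130. The same call with `--obs-col gs --pred-col gs` scores stomatal
conductance (r2=0.9932, mae=0.007 mol m⁻² s⁻¹). `traits.csv` holds the
per-day ε, q<sub>L</sub>, ETR, V<sub>cmax</sub> and g<sub>s</sub>, and
every run writes a JSON manifest with the fully resolved parameters.

The same stages are available as library functions
(`siftraits.retrieve_series`, `fit_ql_par`, `simulate_season`,
`sensitivity_analysis`, ...). `siftraits show-config` prints all resolved
parameter defaults.

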