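# dormsense

Non-invasive monitoring of winter dormancy in deciduous trees from
chlorophyll-fluorescence time series.

## The problem

Temperate fruit trees (the motivating system is orchard apple, *Malus ×
domestica*) pass each winter through endo-dormancy — growth arrest
maintained internally, released only after sufficient chilling — and
eco-dormancy, when only the weather holds the buds back.  Knowing *when*
endo-dormancy is released matters to growers and breeders, but the
classical assay is destructive: cut shoots, force them indoors, wait for
budbreak.  `dormsense` implements an alternative: shoots carry PAM
fluorometers that record an OJIP chlorophyll-fluorescence transient every
hour, and the slow dynamics of the derived JIP-test parameters are mined
for a spectral dormancy marker.

## The method

1. **JIP test.**  Each OJIP induction curve (fluorescence F(t) over
   20 µs–2 s) is condensed to the standard parameters: F₀ and the initial
   slope estimated as intercept/slope of an OLS line over the initial
   linear segment (t ≤ 300 µs), Fm as the curve maximum, and

       Fv/Fm = 1 − F₀/Fm        V_J = (F_J − F₀)/(Fm − F₀)
       M₀ = slope₀/(Fm − F₀)    TR₀/RC = M₀/V_J
       ABS/RC = (TR₀/RC)/(Fv/Fm)
       ET₀/RC = TR₀/RC·(1 − V_J)   DI₀/RC = ABS/RC − TR₀/RC

   Frost-killed tissue loses the O-J-I-P fine structure and its Fv/Fm
   collapses, which drives the frost-damage classifier.
2. **Environment.**  Solar position (NOAA closed-form algorithm) gives the
   zenith angle θ, air mass AM = 1/cos θ, and clear-sky direct insolation
   I_D = 1.353 · 0.7^(AM^0.678) kW m⁻².  Each JIP parameter is regressed as
   X = k₁ + k₂·T + k₃·I_D; a high r² marks a parameter slaved to transient
   weather, a low r² one that can carry slow dormancy information.
3. **Spectral marker.**  The DI₀/RC series is lowpass-filtered (zero-phase
   Fourier filter, cutoff (1 week)⁻¹) and wavelet-transformed (Morlet,
   w₀ = 6, periods 1–512 h).  During eco-dormancy the thermal-dissipation
   flux oscillates with synoptic weather at periods near one week;
   sustained, prominent weekly-band power marks eco-dormancy, and its
   onset is the release date.  Chilling-requirement models (chilling
   hours, Utah, low-chill, North Carolina) provide an independent
   cross-check of the predicted release.

Because the original orchard record is not public, the package ships a
seeded generator (`dormsense.synthetic`) that reproduces the statistical
structure the analysis assumes — temperature harmonics with AR(1) synoptic
noise, linear environmental responses, and an injected weekly-band
eco-dormancy signal — with known ground truth, so every stage is testable
end to end.

## Worked example

```python
from dormsense.synthetic import SeasonConfig, generate_season
from dormsense.model import DormancyModel

dataset, truth = generate_season(SeasonConfig(seed=1))   # two seasons, hourly
results = DormancyModel.from_dataset(dataset).fit()
print(results.summary())
```

```
Dormancy marker analysis
============================================================
parameter:            DI0_per_RC
observations:         17544 hourly
record:               2019-07-01 00:00:00+00:00 .. 2021-06-30 23:00:00+00:00
band:                 168 h (+-0.5 octave)
power threshold:      4.06 (q=0.75 of record)
eco intervals:        2
  release 2020-02-04  window [2020-02-03 .. 2020-02-05]  mean weekly power 37.6
  release 2021-02-06  window [2021-02-06 .. 2021-02-08]  mean weekly power 37.5
phases: vegetation 2019-07-01..2019-10-12, endo 2019-10-12..2020-02-04, ...
```

The generator injected release dates of 2020-02-01 and 2021-02-01: both
are recovered within the ±7-day design tolerance (+3 and +5 days), with a
threshold-sensitivity window of ±1–2 days around each.  The same dataset's
volatility regression for Fv/Fm returns k = (0.700, 0.0039, −0.099) with
r² = 0.64 — the coefficients the generator used, with r² reflecting its
noise level.  An equivalent shell run:

```sh
dormsense --seed 1 --out-dir demo run      # all stages, CSV outputs + summary
```

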