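# Methods

## Scope and data model

`dormsense` analyses two measurement streams from a monitored tree: hourly
OJIP chlorophyll-fluorescence transients (per-curve log-spaced times in µs
and intensities in arbitrary units) and hourly weather-station records.
All timestamps must carry UTC offsets; internal computation is in UTC.
The central in-memory container is `AlignedDataset`: one hourly grid, one
column per JIP parameter / weather channel / solar quantity, and a
per-cell validity mask.  Statistics are always computed on masked data;
the zero written into cleaned cells exists only for raw-compatible CSV
export.

## JIP-test estimation

F₀ and the raw initial slope are the intercept and slope of an OLS line
over all samples with t ≤ 300 µs (configurable).  The 300 µs default
reflects the near-linearity of the O→J rise below that time; at least
three samples are required.  Fm is the global maximum rather than the
final point so that curves that decline after an early peak (frost-killed
tissue) are still summarized.  F_J and F_I are the samples nearest 2 ms
and 30 ms; if the nearest sample is more than a factor 1.5 from the
nominal time the result is flagged `degraded`.  Other `degraded`
conditions: non-positive fitted F₀ (the observed minimum is substituted),
Fm ≤ 1.05·F₀, V_J outside (0,1), clipped negative intensities.  A flat
curve, or Fm ≤ F₀, is `invalid` (all values NaN).  The algebraic
identities DI₀/RC = ABS/RC − TR₀/RC and ET₀/RC = TR₀/RC·(1 − V_J) hold by
construction to machine precision, and all ratio-based parameters are
exactly invariant under rescaling F → aF; the test suite checks both on
randomized curves.

Frost damage is called from shape: `damaged` when Fv/Fm < 0.2, or when
both the J and I step prominences — the rise of smoothed relative variable
fluorescence V(t) across 1→4 ms and 15→60 ms on log-time — fall below
0.05.  The dual rule mirrors how damaged curves differ from healthy ones:
collapsed amplitude and loss of the J-I-P fine structure.  V(t) is
smoothed with a 9-point moving average on a 200-point uniform log₁₀-time
grid; the smoothing only stabilizes the prominence read-out and does not
enter any exported parameter.

## Solar geometry and insolation

Solar elevation uses the NOAA closed-form (Meeus-class) algorithm;
agreement with an independent PSA-algorithm implementation is ≤ 0.01°,
two orders of magnitude inside the 0.5° accuracy the insolation model
needs.  Refraction is ignored — the insolation law is already a clear-sky
idealization.  Direct insolation is I_D = 1.353·0.7^(AM^0.678) kW m⁻²
with AM = 1/cos θ; for θ ≥ 90° the air mass is undefined (reported NaN)
and I_D = 0.  I_D is strictly decreasing in θ and bounded by
1.353·0.7 ≈ 0.947 kW m⁻² overhead.

## Chilling models

Four stepwise chill-unit models ship as an editable CSV of temperature
bins ([t_low, t_high) → weight): chilling hours (1 per hour in 0–7.2 °C),
Utah (graded, negative above 16 °C), low-chill and North Carolina.  The
Utah table (0 below 1.4 °C; 0.5 for 1.4–2.4; 1.0 for 2.4–9.1; 0.5 for
9.1–12.4; 0 for 12.4–15.9; −0.5 for 15.9–18.0; −1.0 above 18 °C) is the
tested reference; the low-chill and North Carolina tables are transcribed
from their commonly tabulated published breakpoints and are editable in
place.  Accumulation requires a gap-free hourly series; an optional
zero floor for the running total is off by default, since published
practice varies on whether warm-spell negation may drive the total
negative.  Release is predicted as the first hour the cumulative sum
meets the requirement; apple cultivars typically need 900–1500 CU.

## Preprocessing

Weather is linearly interpolated in time onto the fluorometer timestamps;
cells bracketed by a source gap longer than 6 h (configurable), or outside
the weather range, stay masked — alignment never extrapolates.  Outlier
cleaning applies two rules per JIP column: negatives, and values exceeding
ten times the parameter's upper normal bound, are set to zero and masked.
Default normal ranges: Fv/Fm ∈ [0, 0.87] (the canonical healthy-plant
ceiling), V_J ∈ [0, 1], per-RC fluxes ∈ [0, 20].  The operation is
idempotent.  `regularize` snaps to an exact hourly grid and makes the
series gap-free for the spectral stages: gaps ≤ 24 h are filled by linear
interpolation, longer gaps by the column's lowpass trend (those cells stay
flagged invalid); any column more than 50 % missing is an error.

## Time-frequency analysis

**Lowpass.**  Zero-phase frequency-domain filter: unity gain below,
zero above, and a raised-cosine transition band of width (1 week)⁻¹
centred on the (1 week)⁻¹ cutoff.  The series is reflect-padded by one
cutoff period per side to suppress wrap-around.  The filter is exactly
linear and passes an 8-week sinusoid at ≥ 99 % while attenuating the
diurnal cycle to ≤ 1 %, which the tests verify against the designed
response curve.

**Wavelets.**  Continuous Morlet transform (w₀ = 6) in the standard
Torrence–Compo FFT formulation, 8 voices per octave over Fourier periods
1–512 h, zero-padded to a power of two.  Scale converts to period via
λ/s = 4π/(w₀ + √(2 + w₀²)) ≈ 1.033.  Power is normalized by the series
variance so detection thresholds transfer across parameters.  The cone of
influence uses the e-folding time √2·s.  Weekly-band power is the mean
power within ±half an octave of 168 h, masked wherever the cone of
influence does not reach the top of the band.

**Dormancy detection.**  The spectrogram reading is operationalized as a
rule with four configurable constants:

- threshold θ_p = 75th percentile of the record's weekly-band power;
- eco candidates are maximal runs with power > θ_p lasting ≥ 14 days;
  qualifying runs closer than 7 days merge;
- a candidate is accepted only if its median power is ≥ 10× the record's
  median — the "prominent peak" requirement.  Without it no record could
  ever report "no eco-dormancy": any series exceeds its own 75th
  percentile a quarter of the time, and because the weekly-band estimator
  is autocorrelated over ~10 days such excursions form fortnight-scale
  runs.  On signal-free simulations those runs reach only 2–5× the median,
  while injected dormancy signals sit at 30× and above, so an order of
  magnitude separates the two populations cleanly;
- detected boundaries are corrected for the estimator's known edge bias:
  the Morlet power envelope is Gaussian in time with sd s/√2 (≈ 4.8 days
  at the weekly scale), so a plateau of height P crossed at θ appears
  widened by (s/√2)·√(2 ln(P/θ)) per side; each interval is shrunk by
  that amount.  Uncorrected onsets ran ~10–12 days early on simulated
  records; corrected onsets are unbiased to within a few days.

Endo-dormancy is the contiguous stretch (≥ 7 days) immediately before an
eco interval during which the lowpass DI₀/RC trend stays below its
vegetation-season median — the sustained decoupling of the dissipation
flux from the environment.  The release date is the start of each eco
interval; the quantile threshold makes the timeline exactly invariant
under affine rescaling of the power series.  `DormancyResults` also
reports a per-release uncertainty window: the spread of release dates when
the detection quantile moves ±0.05.

## Synthetic data

The generator encodes the qualitative structure the analysis assumes, as
falsifiable ground truth:

- **OJIP curves.**  Healthy: relative variable fluorescence is a mixture
  of three logistic rises on log₁₀-time centred at 0.4, 10 and 200 ms
  (weights 0.5/0.3/0.2, widths 0.35/0.45/0.35 dex), chosen so the initial
  segment is linear enough that the F₀ fit recovers the true value to
  ~0.1 % and Fv/Fm ≈ 0.80, V_J ≈ 0.50.  Damaged: a single broad logistic
  (centre 5 ms, width 0.8 dex) with collapsed amplitude (Fv/Fm ≈ 0.1).
  Noise is multiplicative Gaussian.
- **Weather.**  T(t) = 6 °C mean − 14 °C annual cosine (coldest around
  day 20) + 4 °C diurnal harmonic (warmest ~15 h solar time) + AR(1)
  noise (coefficient 0.8, sd 2.5 °C) — a continental cool-temperate
  climate.  UV is clear-sky insolation times a smooth stochastic cloud
  factor in [0, 1]; other channels are plausible baselines plus noise.
- **JIP series.**  Each parameter follows X = k₁ + k₂T + k₃I_D + AR(1)
  noise (e.g. Fv/Fm: (0.70, 0.004, −0.10), noise sd 0.03; DI₀/RC:
  (1.0, 0.01, 0.6), noise sd 0.12), clipped to physical ranges.  Injected
  phase structure per season: endo (Oct 15–Jan 31) attenuates the DI₀/RC
  response coefficients ×0.3, producing the characteristic decline of the
  dissipation flux during deep dormancy; eco (Feb 1–Apr 10) adds a 168-h
  sinusoid of amplitude 0.25 with a season-specific random phase.  That
  amplitude puts the eco/off-season weekly-band power ratio near 20:1 —
  within the intended order of magnitude for a "prominent" marker while
  keeping the detector's prominence gate unambiguous.  Phase labels,
  release dates and damage labels are returned as ground truth.

What the generator does **not** emulate: sensor drift and cross-sensor
calibration offsets, non-Gaussian and non-stationary noise, gaps beyond
simple random missingness, cumulative (memory) effects of cold and light
exposure, and any mechanistic photosynthesis model.  Passing end-to-end
tests therefore demonstrates that the pipeline recovers the signal
structure it is designed for, not that real orchard data will be as
clean; in particular the real analysis reported much weaker volatility
fits for per-RC fluxes than the generator's linear world produces.

## Numerical and design choices

- Problem sizes: end-to-end validations use ten seeded two-season hourly
  records (~17.5k samples each); spectral unit checks use 20–30-week
  sinusoids.  These sizes make every estimator's own noise floor small
  relative to the tolerances being checked.
- Statistical tolerances follow the estimators' sampling theory: V_J is a
  single-sample read-out, so generator-recovery is asserted as
  unbiasedness across seeds rather than per curve; OLS coefficient
  recovery allows the expected rate of >3-SE excursions among 60
  standard-normal z-scores.
- Pearson/Spearman matrices use pairwise-complete observations (masking
  is per cell); midday/midnight subsets are defined by the daily solar
  elevation extremum ±1 h rather than clock time.
- Interpolation is linear in time everywhere; wind direction and other
  angular channels are excluded from interpolation.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; fixed seeds give bit-identical outputs.

## Known limitations

- The detection rule's constants (quantile, durations, prominence) are
  calibrated on the synthetic signal model; real records with weaker
  eco-dormancy oscillations (mild winters) may need a lower prominence
  gate, at the cost of false positives.
- The chilling-model tables for low-chill and North Carolina are
  transcriptions; users with authoritative tables can replace the CSV.
- The volatility regression deliberately ignores cumulative exposure;
  its r² is a screening metric, not a predictive model.
- Endo-dormancy boundaries are detected only relative to an eco interval;
  a season whose eco phase is missed reports no endo phase either.
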