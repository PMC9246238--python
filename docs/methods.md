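# Methods

## Scope and data model

`dendroflux` analyses continuous dendrometer-band records of tropical
trees: stem girth (cm) logged every 30 minutes, 48 slots per calendar
day, alongside soil moisture potential (SMP, kPa, ≤ 0, measured by
several equitensiometers per logger station at ~20 cm depth), logger
temperature at 14:00 (TEMP, °C) and daily rainfall (mm). The response
of interest is the daily girth increment

    gthi_i = (gthm_{i+1} − gthm_i) · 10³   [cm·10⁻³ per day]

where `gthm` is the mean of a day's 48 girth values, computed only for
days with all 48 slots present. Increments are formed from daily means
(not daily means of finer increments) and an increment spanning a gap
in `gthm` is missing. Increments attach to their left endpoint, so a
period boundary day carries the increment leaving it.

## Preprocessing

* **Calendar alignment.** Every series is reindexed onto a common frame
  of whole days (midnight slot opens the day); slots absent from the
  input become explicit missing values and observed values are never
  altered.
* **Gap imputation.** Interior runs of one or two missing values — at
  the half-hour level and again at the day level — are replaced by the
  mean of the bounding pair and flagged. Longer day-level outages (band
  repairs; up to ~17 days in practice) are bridged by the same rule only
  when explicitly requested (`max_day_gap`), since a long linear bridge
  flattens the local increments.
* **SMP cleaning.** Two per-sensor variants: *offset* (subtract the
  sensor's upper 0.95-quantile — type-7 estimator, linear interpolation
  of order statistics — then clamp positives to zero) removes the small
  positive conversion offsets; *strict* clamps to [−1000, 0] kPa,
  discarding implausible extreme lows. The logger-temperature
  correction −(T − 20)/4 kPa (≈ 2.5 kPa at 30 °C) is applied before
  cleaning; a configuration switch allows the other order, which the
  available evidence does not distinguish.
* **Station averaging.** Unweighted per-day means over a station's (or
  topographic class's) sensors; a day is missing only when all sensors
  are missing.
* **Dry spells.** Maximal runs of more than 3 consecutive days (≥ 4)
  with station-averaged offset SMP ≤ −150 kPa (strict: ≤ −100 kPa). A
  missing day conservatively terminates a run.

## Regression model

For one band the model is

    gthi_i = β₀ + β_S · (−√|SMP_{i−1}|) + β_T · TEMP_i + ε_i,
    ε ~ stationary, invertible Gaussian ARMA(p, q),  (p, q) = (2, 2)

The −√|·| transform tames the strong left skew of SMP. Lags {0, 1, 2}
are scanned for both predictors on a common response span; the lag-1
SMP and lag-0 TEMP terms carry the physiological interpretation
(yesterday's soil water state, today's evapotranspiration pull).
Single-term, two-term and interaction forms are available; interaction
fits centre both predictors first to tame collinearity (flagged in the
output, since centring changes the main-effect interpretation).

**Estimation** is exact Gaussian maximum likelihood. For candidate ARMA
parameters — optimised on an unconstrained scale via the
partial-autocorrelation transform, so every iterate is stationary and
invertible — the regression coefficients are profiled out by GLS and
the innovation variance concentrated. The whitening uses the
innovations algorithm (one-step prediction errors), which is exactly
equivalent to solving against the Cholesky factor of the Toeplitz ARMA
autocovariance but costs O(n) per design column. ML rather than REML is
used so likelihoods are comparable across the order-selection grid; a
switch is not provided because the AIC grid is the only consumer.
The optimizer starts at white noise (all zeros) with a fixed,
deterministic jitter sequence of restarts, so fits are reproducible
without a seed; on persistent failure the fit falls back to q − 1, the
remedy that also resolves occasional non-invertible iterates.
Standard errors come from the GLS covariance at the fitted ARMA
parameters with σ² estimated on n − k denominators; t-ratios use
Student-t with n − k df (the normal approximation is anti-conservative
at these sample sizes). With (p, q) = (0, 0) the fit reduces to OLS to
machine precision, which the tests assert.

**Order selection** scans p ≤ 2, q ≤ 2, d ∈ {0, 1} with the exogenous
term included, scoring by AIC on a common effective sample (series less
its first value; differenced when d = 1) so values are comparable.
Ties break to smaller p + q, then smaller q. Selected d is reported but
production fits always model `gthi` undifferenced: the increment is
itself a difference of girth, and differencing it again obscures the
physiological reading. Non-converging grid points are skipped.

**Size standardisation.** Coefficients are scaled to a 50 cm-gbh
reference by ×50/gbh for cross-tree comparison, and back-scaled where
predictions on the original scale are needed.

## Rain residualisation (dry period)

Showers during a dry period transiently re-wet and swell the dried
bark, so the band reads girth change that is not tree water status.
Per band, `gthi` on days with ≥ 1 mm rain is regressed by OLS on a
quadratic in ln(rain); on the remaining days (0 mm, plus trace rain
< 1 mm, pooled because a trace shower cannot wet the bark appreciably)
the plain mean is taken. Pooling all days into one regression would be
grossly heteroscedastic because most dry-period days are rain-free.
Residuals about the curve / zero-mean replace `gthi` downstream. Fits
with current-day and previous-day rainfall are both available; which
one a band uses is a configuration choice, because a minority of bands
respond to the previous day's showers.

## Non-stationarity handling

The ACF of squared residuals screens for variance episodes: verdict
*strong* when at least two of lags 1–3 exceed ±1.96/√n and the
Ljung–Box P over the first three lags is < 0.01. Strong cases can be
fitted by GARCH(1,1) Gaussian quasi-ML (ω > 0, α, β ≥ 0, α + β < 1;
recursion initialised at the sample variance, vectorised through an
IIR filter) to characterise the episode. The estimate that replaces
the full-series fit, however, is the three-way subseries split: fit
each part separately (equal thirds, or custom breakpoints isolating
the volatile stretch), then combine the two outer parts — coefficient
as their mean, SE as the root-mean-square of their SEs, t as the mean
t, P from Student-t with n/3 − 2 df (181.3 for the 550-day series).
The root-mean-square is used for the combined SE; a geometric mean of
SEs would not propagate variances correctly.

## Granger causality

Whether SMP (or TEMP) forecasts `gthi` beyond its own history:
restricted OLS of y_t on a constant and p = 2 own lags versus the
unrestricted model adding 2 lags of x; F = ((RSS_r − RSS_u)/2) /
(RSS_u/(n − 5)) against F(2, n − 5). A constant x is rejected as a
singular design.

## Diurnal analysis

Within-day girth change is `gthch_t = ((girth_t − girth_1)/girth_1)·10⁴`
relative to the midnight slot; any missing slot voids the day. The
10⁴ multiplier is kept (it puts values in the observed 0–20 range) even
though such values are conventionally read as "per mille". The long wet
period is tiled with consecutive 18-day blocks from its start (550 days
→ 30 blocks, trailing 10 days dropped); block mean profiles, treated as
independent replicates, give a per-slot Student-t envelope
mean ± t_{0.99, n−1}·SD/√n (level configurable; 0.99 default). A
dry-period mean profile outside the envelope at any slot rejects
equality of wet and dry diurnal behaviour at P < 0.01. Dry-period
profiles exclude days with ≥ 10 mm rain (bark re-wetting); the wet
period is not filtered by default (soil state does not change the
always-wet bark), switchable.

## Synthetic data generator

The generator emulates the study conditions with known truth so every
stage is testable without field data:

* **Rainfall**: zero-inflated gamma, wet-day probability 0.60, gamma
  (0.7, 18) mm — an everwet ~2800 mm/yr regime — with a configured
  rain-deficit window (10.02–18.06.2010 by default) where showers are
  rarer (p = 0.45) and light (gamma (0.7, 2.5)), plus a 6% admixture of
  heavier showers so the ≥ 10 mm exclusion rule is exercised. The
  deficit is one continuous window: the dry period it produces is dry
  throughout, which is what the rain residualisation assumes; a
  three-spell calendar remains expressible through configuration.
* **Temperature**: AR(1) around 26.9 °C (ρ = 0.6, SD 0.7), clipped to
  [23.5, 31.5], +0.8 °C inside the deficit (clear skies), which also
  yields the expected negative TEMP–SMP correlation.
* **SMP**: a per-station bucket, SMP_t = clamp(SMP_{t−1} + 4·rain_t −
  1.6·max(TEMP_t − 20, 0), −500, 0) kPa. Under the wet regime this
  pins near zero with occasional dips (rarely below −100), and during
  the deficit falls to −250…−500, matching the observed nine-fold
  wet/dry contrast. Sensors read the station bucket plus a positive
  per-sensor bias (uniform 2–12 kPa, exercising the offset transform),
  Gaussian noise (SD 3 kPa) and rare extreme-low glitches (−2000 kPa,
  exercising the strict transform).
* **Trees**: 18 bands at 4 stations with the target study's sizes
  (27–117 cm gbh) and guild structure; planted size-standardised
  responses are mixed-sign — positive for most small understorey trees,
  negative for the large overstorey ones. The daily girth path
  integrates the linear predictor plus ARMA(2,2) noise (AR 0.55, −0.12;
  MA 0.22, 0.10; innovation SD 2 cm·10⁻³). Half-hourly values modulate
  each day's mean with a zero-mean diurnal shape (peak ~10:00, trough
  ~15:30), so daily means recover the path exactly and, with noise off,
  recomputed increments reproduce the planted predictor exactly.
* **Bark artefact**: b₁·ln(rain) + b₂·ln(rain)² added to the day's
  increment on days with ≥ 1 mm rain, *only* when the day lies inside a
  sustained rain deficit and the previous day's soil was drier than
  −100 kPa — bark dries out over weeks of drought, not from one damp
  day in an everwet stretch. Adding the term to the increment (rather
  than as a transient level bump) is exactly the additive structure the
  quadratic residualisation removes, which makes the planted artefact
  recoverable and the adjustment property testable.
* **Missingness**: independent single-slot (0.3%) and paired-slot
  (0.1%) gaps, imputable by the short-gap rule, plus one long multi-day
  outage on two designated bands (12 and 17 days), bridged only on
  request.

Ground truth (per-tree coefficients, bark terms, deficit windows) is
emitted separately and never written into analysis-facing tables.

### What the generator does not emulate

No hydraulic architecture, stomatal control, root-depth differences
(negative responses are planted directly, not mechanistically derived),
spatial competition, seasonality, sensor drift, or thermal expansion of
bands. Passing recovery tests therefore shows the *statistical*
pipeline is correct under its stated error model, not that the model is
a complete description of real dendroband data.

## Problem sizes used in validation

Calibration checks use 200 replicates of the 550-day wet scenario for
CI coverage and bias, 1000/200 replicates at n = 300 for Granger size
and power, 100 seeded climates for dry-spell recovery, 30 paired dry
replicates for the rain-adjustment bias comparison, and 2000 replicates
for envelope coverage; these sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerance bands.

## Numerical choices and degenerate inputs

* Quantile estimator: type 7 (NumPy default), recorded for
  reproducibility; offset cleaning refuses sensors with < 20 values.
* The envelope requires ≥ 3 sub-period profiles; GARCH warns under 100
  observations; order selection refuses series shorter than
  10·(max_p + max_q); the rain fit refuses fewer than 6 rain days or 3
  zero-rain days and reports the counts.
* A neighbour at zero distance makes the BA/d weight undefined and is
  rejected rather than silently skipped.
* agr uses 365.25 d/yr; stem basal area assumes circular stems,
  BA = gbh²/(4π).
* Coefficient prediction from diurnal maxima uses the full prediction
  SE (leverage plus residual components) and refuses < 3 known trees.

## Known limitations

GLS standard errors condition on the fitted ARMA parameters; the cost
is a small undercoverage (~1 pt at n = 550) relative to nominal.
The subseries recombination df (n/3 − 2) is a pragmatic convention, not
an exact distributional result. GARCH(1,1) quasi-ML on series under a
few hundred observations is weakly identified. The CLI covers the
simulate/fit workflow; diagnostics beyond it are library calls.
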