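# Methods

This note documents the models and procedures implemented in `heatbands`,
the assumptions behind them, the choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not
establish.

## Exposure dating and trimester windows

Conception is dated by subtracting gestational age in completed weeks from
the birth date.  Gestation is divided into trimesters of 12, 14 and 13
weeks from conception — half-open day intervals `[c, c+84)`,
`[c+84, c+182)`, `[c+182, c+273)` that tile the 39-week (273-day)
analysis schedule.  Exposure is scored over this fixed schedule for every
birth, *including preterm births whose third-trimester window extends past
the delivery date*.  Truncating exposure at birth would make the exposure
mechanically a function of the outcome (earlier birth ⇒ less exposure),
biasing the regression; the fixed schedule keeps exposure exogenous to
gestational length.  A `truncate_at_birth` switch exists for sensitivity
analysis only and is off by default.

## Heat metrics

All band intervals are half-open `[lower, upper)`, so a band printed as
"20–24.99" is `[20, 25)` and a temperature of exactly 25.0 falls in the
next band up.  The five built-in metrics per trimester:

| metric | regressors / trimester | omitted reference |
|---|---|---|
| benchmark | day counts, daily max in <20, 20–25, 25–30, 30–35, 35–40, 40+ °C | 25–30 |
| trimester_average | mean daily max | — |
| heatwave_count | number of heatwave events (by start date) | — |
| max_and_min | benchmark + daily-min counts in <5, 5–10, 10–15, 15–20, 20–25, 25+ | 25–30 (max), 15–20 (min) |
| wet_bulb | daily-average WB counts in <10, 10–15, 15–20, 20–25, 25+ and daily-max WB counts in <10, 10–15, 15–20, 20–25, 25–30, 30+ | 15–20 (avg), 20–25 (max) |

Omitted reference bands are computed and carried in the exposure table
(flagged in `frame.attrs["omitted"]`) but excluded from design matrices.
Materialising them keeps the conservation identity testable: for every
banded metric the per-trimester counts, including the omitted band, sum
to exactly 84/98/91 days.

Heatwave events straddling a trimester boundary are attributed once, to
the trimester containing the event's first day; the attribution rule is a
package choice (any single-count rule would do, and only the count enters
the model).

## Thermal derivations

*Daily mean* is `(tmax + tmin)/2`.  *Wet-bulb temperatures* use Stull's
single-equation empirical fit in temperature and relative humidity,
accurate to a few tenths of a degree for RH ≳ 5 % and temperatures
between about −20 and 50 °C (a warning is emitted outside this envelope).
The daily-maximum wet bulb is `Stull(tmax, rh)`.  Because the generator
provides one RH value per day, the daily-average wet bulb is defined as
`Stull(tmean, rh)` rather than an average of sub-daily wet bulbs; only
monotone band membership is consumed downstream, so this choice affects
band boundaries, not the logic of any later stage.

*Excess Heat Factor.*  For day *d*, let T3 be the mean daily-mean
temperature over days {d−2, …, d} and T30 the mean over the 30 days
ending at d−3 (the acclimatisation window deliberately excludes the
current 3-day block).  Then

```
EHI_sig  = T3 − baseline
EHI_accl = T3 − T30
EHF      = EHI_sig × max(1, EHI_accl)      (°C² semantics; only the sign is used)
```

The first 32 days of a series are unscored.  The default `baseline` is the
long-term location mean of the daily mean temperature; the operational
convention of the 95th percentile is available as `baseline="p95"`.  With
the mean baseline, roughly half of warm-season days have a positive
significance term, so detected "heatwaves" (runs of ≥ 3 positive-EHF
days) are more frequent and longer than under the percentile variant —
about 10 per year with ~15-day mean duration in the synthetic tropical
zone, versus the 2–3 per pregnancy typical of percentile-based
definitions.  Downstream stages treat the event count as an opaque
regressor, so the choice shifts the metric's scale, not the pipeline's
mechanics.

## Geographic clusters

Locations are grouped by complete-linkage agglomerative clustering on
pairwise haversine distances (Earth radius 3958.8 miles), cutting the
dendrogram at 50 miles.  Complete linkage is the only standard
agglomerative criterion whose merge height equals the merged cluster's
diameter, so the cut directly enforces "maximum 50-mile distance between
points" read as a *diameter* bound; reading it as a linkage threshold
would permit chains wider than 50 miles, and the diameter reading is the
conservative one.  Every produced assignment is audited post hoc against
the bound.  Points are processed in location-id order, making the
partition invariant to input order.

## The fixed-effects linear probability model

The outcome is regressed on the heat regressors and covariates (first
pregnancy, Aboriginal status, maternal age in 5-year bands one-hot with
25–29 as reference) with two absorbed fixed-effect groups: location ×
conception-month × sex, and calendar month-year of conception.  A linear
probability model is used deliberately — coefficients are
percentage-point effects per exposure day, and predicted values may leave
[0, 1]; they are clipped (with a flag) only in counterfactual summaries.

*Absorption* is alternating within-group demeaning of the outcome and
regressors, iterated until the largest absolute change in any entry is
below 1e-10 (cap 10,000 sweeps; non-convergence is an error naming the
achieved tolerance).  With one FE group a single sweep is exact.
Collinear columns are detected by pivoted QR and dropped with a log.

*Cluster-robust covariance.*  The sandwich estimator sums score
contributions within geographic clusters and applies the finite-sample
factor `G/(G−1) × (N−1)/(N−K)`, with K counting the absorbed fixed
effects (levels of both groups minus one shared constant) as well as the
retained regressors — the convention of Stata's `areg`, chosen so the
absorbed path is exactly comparable with an explicit dummy-variable
regression.  The equivalence (coefficients, cluster SEs, Wald statistics,
within R²) is asserted to 1e-6 relative in the test suite, including a
cross-check against statsmodels' clustered OLS on the dummy
representation.

*Joint F test.*  For a heat-metric term group of q coefficients,
`F = b'V⁻¹b / q` on the cluster-robust covariance with denominator
degrees of freedom G − 1.  A caveat that matters in practice: when q is
an appreciable fraction of G (for example 30 restrictions with 60
clusters), the estimated q×q covariance block is noisy and the Wald test
over-rejects severely under the null.  This is a property of
cluster-robust Wald tests with many restrictions, not of the
implementation — the dummy-variable oracle reproduces it exactly.  The
package's null-size experiment therefore measures the test's size on a
small term group (the 3-term trimester-average metric), where the size is
near nominal (≈ 3–4 % at the 5 % level, slightly conservative); the
many-restriction distortion is documented here as a known limitation for
interpretation of large-group F statistics.

*Fit statistics.*  The within R² is computed on the demeaned data; its
adjusted version penalises the retained regressor count against the
absorbed-FE-corrected effective sample size.  The AIC is Gaussian,
`−2 lnL + 2p` with `lnL` from the residual sum of squares and `p` the
retained regressors plus intercept and error variance.  Absorbed fixed
effects are excluded from p: all compared models share an identical FE
structure, so their (large, constant) contribution would cancel in every
comparison; a flag includes them for sensitivity.  The AIC is therefore
internally consistent for *ranking* these models and is not comparable
with AIC values computed under other bookkeeping conventions.

## Metric selection

Stage one screens each candidate metric by the joint F test of its heat
terms at level α = 0.05; metrics whose coefficients cannot be jointly
distinguished from zero are set aside with the reason recorded.  Stage
two ranks survivors by AIC (lower is better).  The within adjusted R² is
reported alongside; when the two measures disagree on the winner the AIC
decides — it is the purpose-built tool for comparing a small set of
non-nested working models — and the disagreement is flagged loudly in
the report and the log.  Ties break on fewer regressors, then name order.
The report always lists every candidate, screened or not, and selection
is invariant to the order fits are supplied.

## Counterfactual seasonal predictions

"Typical" weather is the multi-year day-of-year climatology at each
birth's own location: per-day-of-year means of the base fields (tmax,
tmin, RH) over complete reference years, Feb 29 filled from Feb 28, with
derived fields recomputed from the averaged base fields rather than
averaged post hoc.  Two scenarios are built: gestation ending on 15 May
(spanning the hottest nine months — the build-up and wet season in a
monsoonal calendar) and on 15 November (the coolest nine).  Scenario
exposure vectors are computed from the climatology exactly as for real
weather.

The prediction is a partial-effect contrast: predicted cohort rate under
scenario s = observed mean outcome + mean over births of
`(x_s − x_factual)'·b_heat`.  Only heat terms are swapped; covariates and
fixed effects are held at factual values and cancel exactly in the
hottest-minus-coolest difference.  This is the only construction under
which "typical seasonal exposure" is well defined without re-estimating
fixed effects for counterfactual calendars.  Confidence intervals at
68/80/95 % cover the heat-coefficient-driven component only (the observed
baseline rate is treated as fixed), by the delta method on the
cluster-robust covariance with Student-t critical values on G − 1 degrees
of freedom; a parametric-simulation alternative (draws from N(b, V)) is
available and agrees with the delta method to within a few percent of
half-width in the tests.  Reported rates are clipped to [0, 1] with a
flag; the difference is never clipped.

## The synthetic-data generator

The generator emulates the features of a hot-climate birth register
linked to gridded daily weather that the downstream stages are sensitive
to.  Weather per location: daily maximum temperature is an annual cosine
plus stationary AR(1) Gaussian noise; the diurnal range is itself
seasonal plus independent noise (floored at zero), with
`tmin = tmax − range`; relative humidity is a seasonal curve plus a
coupling term proportional to the day's temperature anomaly, clipped to
[0, 100].  Giving the diurnal range its own noise is what reproduces the
key tropical phenomenon: a weak daily max–min correlation (≈ 0.77 under
tropical defaults, against ≈ 0.99 arid), because humid nights keep the
minimum high regardless of the afternoon peak.  A negative
humidity–temperature coupling makes hot anomalies dry, giving the
negative RH–tmax correlation (≈ −0.25) characteristic of monsoonal
climates where the hottest days are the rainless ones.

Zone defaults are set so an average tropical wet-season day spans roughly
25–33 °C (the majority of wet-season days keep their full diurnal range
inside that envelope), the tropical dry season roughly 20–30 °C, and the
arid zone roughly 20–35 °C in summer and 4–20 °C in winter, with seasonal
peaks in early December (tropical build-up) and mid-January (arid).
The default geography scatters 50 tropical and 50 arid locations widely
enough that they collapse to ~60 clusters at the 50-mile bound — the
same order as the ~100 clusters of a territory-wide register, and
comfortably above the largest heat-metric term group (30), which a
full-rank cluster-robust Wald test requires.

The cohort: conception dates uniform over the configured interval
(sampling by conception date avoids the fixed-cohort bias of
birth-date sampling), locations uniform, sex/parity/age-band/Aboriginal
covariates drawn at plausible register frequencies.  The latent preterm
probability is linear in the configured band effects and covariate
effects around a 10 % baseline, clipped to [0, 1] with the clipping
frequency recorded in the truth record (a logistic link is available for
robustness experiments).  By default the heat contribution is centred
within location × conception-month cells — equivalently, the latent
model's fixed-effect terms offset the local seasonal mean of the heat
signal — so the signal operates through exactly the within-cell
variation a fixed-effects regression identifies, the cohort rate stays
at the baseline, and clipping is rare; `center="none"` makes exposure
shift risk levels across locations and seasons too, which is the right
setting for marginal (stratified) comparisons.  Gestational length is
uniform on 28–36 completed weeks for preterm births and 37–42 for term
births; only the 37-week threshold matters downstream.  A birthweight-like
continuous outcome follows an analogous linear process.

The reference planted-effect profile (`MODERATE_BAND_EFFECTS`) puts a
cooler-protective / hotter-risky gradient on minimum- and
maximum-temperature bands at a fraction of a percentage point per
exposure day, the scale at which band coefficients are reported in this
literature, and strong enough to be decisively detectable at n = 10,000.

What the generator does *not* emulate: spatial correlation between
locations beyond shared zone parameters, weather autocorrelation beyond
AR(1), residence changes during pregnancy, seasonality of conceptions, or
any non-heat seasonal risk.  Passing tests therefore demonstrate the
*statistical machinery* — unbiased recovery of a known linear signal,
correct test size on small term groups, selection consistency, CI
coverage — not that any particular real-world effect estimate is
correct.

## Validation experiment sizes

The replicate experiments run on one realised study (100 locations, five
years of weather, cohorts of 10,000 births) and redraw only the Bernoulli
outcome, which is the sole random element once covariates and exposures
are fixed; the design is demeaned and factorised once, making each
replicate fit a cheap triangular solve.  Sizes: 200 replicates for
parameter recovery and CI coverage, 500 for null test size, 100 for
selection consistency, 200 for counterfactual null coverage — enough to
bound the Monte-Carlo error of each reported proportion below about two
percentage points.

## Known limitations

* The linear probability model can predict outside [0, 1]; extrapolated
  counterfactual scenarios far from the factual exposure distribution can
  produce clipped rates (flagged, never silently).
* Large-term-group cluster-robust Wald F statistics over-reject when the
  restriction count approaches the cluster count (see above).
* The AIC's parameter bookkeeping excludes absorbed fixed effects and is
  valid only for comparing models with identical FE structure.
* The EHF mean-baseline default yields more and longer heatwave events
  than the operational percentile definition; use `baseline="p95"` when
  comparability with published heatwave climatology matters.
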