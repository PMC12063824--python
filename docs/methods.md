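# Methods

This note documents the models and procedures implemented in `chlorovar`,
the defaults they use, and the choices made where the design was genuinely
open.  Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sensor QC (`chlorovar.qc`)

15-minute sonde records are converted to daily averages to remove diel
signatures.  Per variable and per calendar day:

* missing points are filled by linear interpolation between the bracketing
  observations, **only inside** the deployment (never extrapolated past the
  first or last observed point);
* the day is omitted when the longest run of consecutive missing points in
  the **raw** (pre-interpolation) record strictly exceeds `qc_max_gap`
  (default 60 minutes).  The inequality is strict: a 4-point (60-minute) gap
  is tolerated, a 5-point (75-minute) gap is not;
* a run of missingness spanning midnight counts toward each day only for
  the portion inside that day's 24-hour window;
* partial days at deployment boundaries are retained only when the
  deployment covers at least 23 hours of the day (92 of 96 grid slots) —
  shorter coverage would bias the mean toward one part of the diel cycle;
* provenance is recorded per date and variable: `observed_complete`,
  `gap_filled`, or `omitted`.

The gap rule is applied per variable, since sensors fail independently
(conductivity and fluorescence probes drop out at different times).

## Multiplicative timescale decomposition (`chlorovar.decomposition`)

Monthly chlorophyll c_ij (year i, month j) is modeled as
`c_ij = Cbar * y_i * m_j * eps_ij` with all factors positive.  Estimators:

* `Cbar` = mean of all observed cells;
* `y_i` = (mean of year i's observed cells)/Cbar, renormalized to unit mean
  over years;
* `m_j` = mean over years of `c_ij/(Cbar*y_i)` at observed cells,
  renormalized to unit mean over months;
* `eps_ij = c_ij/(Cbar*y_i*m_j)`, which makes the reconstruction identity
  exact at every observed cell (tested at 1e-10 relative tolerance) and
  absorbs any imbalance from missing cells into the residuals.

Normalizing **both** y and m to unit mean keeps the three components on the
same dimensionless scale, so their sample (n−1) standard deviations are
directly comparable; on complete matrices both means equal 1 exactly.
Missing cells are skipped in every mean — no imputation (the estimator must
tolerate, e.g., a weather-prevented month).  The series is decomposed on
the raw scale, not log-transformed: the model is multiplicative and the
reported quantities are the dimensionless coefficient SDs.  Years with no
observations are dropped with a warning; at least two years are required.
The variability partition ranks (annual, seasonal, residual) by descending
SD with ties kept in that input order.

On noiseless constructed matrices the estimators recover the constructing
factors exactly; under mean-one lognormal noise (sigma 0.3, 30 years) the
estimates averaged over 200 seeds stay within 3 Monte-Carlo standard errors
of truth (the estimator is a ratio estimator, so an O(sigma^2/n) bias
exists but sits below that resolution).

## Bloom detection (`chlorovar.blooms`)

A trigger is an ordered pair of observed days (t1, t2), at most
`bloom_window − 1 = 3` calendar days apart, with
`chl(t2) − chl(t1) ≥ bloom_delta = 50` µg/L.  Choices fixed here:

* the comparison is inclusive (a rise of exactly 50 qualifies);
* the rise is endpoint-to-endpoint by default; a `minmax` variant (best
  ordered min-to-max pair within each 4-day span) is available via
  `PipelineConfig.rise_criterion` for records where the daily sequence dips
  inside the span;
* pairs may bridge omitted days — only the endpoints must be observed —
  because gappy records still contain real events.

Triggers are clustered by single linkage on their end dates with gap ≤
`merge_window = 14` days.  Each cluster's day 0 is the maximum-chlorophyll
day over the cluster span extended by the context window (ties broken by
earliest date); clusters whose peaks still fall within 14 days of each
other are merged again, so final events are pairwise separated by more than
the merge window peak-to-peak and merging is idempotent.  The analysis
window is day 0 ± `event_context = 14` days, trimmed to the available
record (events at a record boundary have n < 29).

The detector is verified against exhaustive brute-force pair enumeration on
randomized records, and against the synthetic generator's planted ledger.

## Driver-model selection (`chlorovar.drivers`)

Candidate predictors per event: daily average wind speed, its one-day lag,
daily maximum sustained wind speed, water temperature, and rain.  Pipeline:

1. **Event frame.**  One row per window date with observed chlorophyll;
   complete cases are fixed once so every candidate model is fitted on the
   same n (AICc values are only comparable on identical data).  Meteorology
   must cover the window plus the day before (needed for the lag); if it
   does not, the event is flagged not-analyzable rather than modeled on
   partial forcing — this coverage filter is why not every detected event
   yields a model.  Zero-variance candidates (e.g. rain during a rain-free
   event) are dropped with a note.
2. **CCF lag screen.**  The lag-1 wind term enters the candidate set iff
   the Pearson correlation between previous-day wind and chlorophyll
   reaches the white-noise band `1.96/sqrt(n)`.  Only the one-day lag is
   screened; longer biological lags are outside scope.
3. **Collinearity pruning.**  While any candidate pair has |r| ≥ 0.7, the
   highest-|r| pair is resolved by dropping the member less correlated with
   chlorophyll (ties: later candidate order).  The 0.7 threshold is a
   conventional cutoff, configurable via `collinearity_r`.  In practice
   this step arbitrates between average and maximum wind speed, which are
   strongly coupled.
4. **Exhaustive enumeration.**  All 2^p additive OLS subsets (including
   intercept-only) ranked by `AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)`
   with k = slopes + intercept + residual variance; subsets with
   n − k − 1 < 1 are skipped, and p > 12 is refused.  Ties break toward
   fewer terms.  A numerically exact fit (RSS at rounding level) maps to
   −inf so it ranks first.
5. **Backward elimination** from the AICc-best model: repeatedly drop the
   largest-p term while any p > α = 0.05.  The final model either has every
   term significant or is the intercept-only model flagged "no significant
   model".  The overall model p is the final fit's F-test.

Enumeration, AICc and elimination are each tested against independent naive
re-implementations (plain normal-equation solves and t-tests) on random
frames.

## Sampling-frequency simulation (`chlorovar.subsampling`)

The useable-day record (however long; a 171-day "year" in the motivating
case) is split into contiguous blocks whose lengths differ by at most one
day, extra days going to the earliest blocks (171 → quarters 43/43/43/42,
months 3×15 + 9×14).  Each of `n_sims = 1000` simulations draws one day
uniformly per block using a per-simulation RNG substream spawned by counter
from the seed, so results are reproducible and independent of execution
order.  The report compares averaged per-simulation mean/min/max with the
raw record and derives the max deficit (raw max − average simulated max),
min excess, and percent reduction of the maximum.

## Synthetic-data generator (`chlorovar.synthetic`)

The generator emulates a wind-driven, low-inflow subtropical lagoon.
Daily chlorophyll:

    chl(t) = C * Y(year) * M(month) * (1 + sum of bloom kernels) * exp(eps_t)

with `eps_t ~ Normal(−sigma²/2, sigma²)` so the noise factor has mean one.
Defaults and why:

| parameter | default | rationale |
|---|---|---|
| grand mean C | 50 µg/L | a eutrophic-lagoon baseline; rises ≥ 50 µg/L then mean an approximate doubling |
| annual factors | 1.35…0.65 (mean 1) | a gentle multi-year decline across 5 years |
| monthly factors | cosine, peak Jun–Jul, amplitude 0.35, mean exactly 1 | early-summer seasonal peak |
| noise sigma | 0.35 | puts the fitted residual SD in the high-sub-monthly regime typical of such systems |
| wind | seasonal mean 5.5 ± 1.0 m/s, AR(1) φ = 0.6, innovation SD 1.5 | persistent coastal wind with multi-day weather memory |
| wind max | 1.4 × wind_avg + half-normal(SD 2.0 m/s) | daily max 2-min sustained wind tracks the daily mean strongly but not deterministically (r ≈ 0.9, max/mean ≈ 1.8), as in coastal station records; the two remain collinear enough (> 0.7) to exercise the pruning step |
| rain | wet-day p = 0.15, Gamma(0.6, 12 mm) | semi-arid: mostly dry days, occasionally heavy rain |
| temperature | 20 ± 10 °C sinusoid, peak mid-July | the ~10–30 °C subtropical annual cycle |
| salinity | baseline 30, −0.15 per mm rain, +0.03/day evaporation, clipped 8–46 | sharp rain-driven drops, slow hypersaline recovery |
| bloom kernels | triangular, rise/fall 1–3 days, relative amplitude 1.5–4, triggered when (lagged) wind exceeds its month-of-year 90th percentile, 30-day refractory | ephemeral (< 3 day) wind-triggered blooms |

Every planted bloom is recorded (peak date, amplitude in µg/L, duration,
driver, lag) so detection and recovery tests compare against truth.  The
15-minute expansion multiplies the daily value by `1 + a·sin(2π·hour/24)`;
the sinusoid has exactly zero mean over the 96-point day, so daily
averaging inverts it, and planted gaps exercise the QC boundary.
`generate_driver_event` builds single-event regression frames with
`chl = c0 + beta·wind(t−lag) + centered lognormal noise`, the noise scaled
to a target coefficient of determination (default 0.6, the middle of the
informative 0.4–0.8 range).

What the generator does **not** emulate: autocorrelated daily residuals
(noise is i.i.d. across days, which makes threshold detection *harder* than
on smooth real records and inflates spurious triggers during high-biomass
months), sensor drift and fouling, nutrient or grazing dynamics, advective
patchiness, and tidal signals.  Tests passing on these synthetics therefore
demonstrate correctness of the algorithms under known structure, not field
performance of any threshold.

## Problem sizes

Defaults used by the analysis scripts and acceptance run: 2-year daily
records for detection, a 5-year monthly program (59–60 grabs) for
decomposition, 200 seeded replicates per driver-recovery scenario, 1,000
resampling simulations per frequency, and 200 seeds for the noisy
decomposition-recovery check.  All are the package's own choices of
scenario scale and complete in seconds to a few minutes on one core.

## Known limitations

* The decomposition's month coefficients are poorly determined when a month
  is observed in few years; no shrinkage is applied.
* Backward elimination inherits the usual stepwise caveats (post-selection
  p-values are optimistic); the reported per-term p-values are conditional
  on the selected model.
* The CCF screen tests only lag 1 and uses the white-noise band, which is
  approximate for autocorrelated series.
* Event windows overlapping record boundaries shorten n and reduce the
  power of the per-event models, exactly as in real deployments.
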