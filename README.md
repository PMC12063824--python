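# chlorovar

Timescales and drivers of chlorophyll variability in estuarine monitoring
data.

Shallow, long-residence-time lagoons can build and lose phytoplankton
biomass in days: wind resuspends cells and sediment nutrients, ephemeral
rain pulses deliver fresh nutrients, and blooms often last less than three
days — far below the resolution of monthly or quarterly monitoring.
`chlorovar` is a tested pipeline for asking, from a combination of
high-frequency sonde records and low-frequency grab samples:

1. **At which timescale does chlorophyll vary most?**  A monthly series
   c<sub>ij</sub> (year *i*, month *j*, µg/L) is decomposed multiplicatively,

   c<sub>ij</sub> = C̄ · y<sub>i</sub> · m<sub>j</sub> · ε<sub>ij</sub>,

   into a grand mean, unit-mean annual coefficients y<sub>i</sub>, unit-mean
   seasonal coefficients m<sub>j</sub>, and sub-monthly residuals
   ε<sub>ij</sub>.  The sample standard deviations of {y}, {m}, {ε} are
   dimensionless and partition variability into interannual, seasonal, and
   event-scale components.
2. **What drives blooms?**  On the QC'd daily series, a bloom trigger is a
   chlorophyll rise ≥ 50 µg/L within a 4-day span; triggers within 14 days
   merge into one event with day 0 at peak chlorophyll.  For each event's
   ±14-day window, additive linear models over wind (daily average, one-day
   lag, daily maximum), temperature and rain are enumerated exhaustively,
   ranked by AICc (k counts intercept + slopes + residual variance), pruned
   for collinearity (pairwise |r| ≥ 0.7), and simplified by backward
   elimination to an all-significant model (α = 0.05).  A cross-correlation
   screen (|r(lag 1)| ≥ 1.96/√n) decides whether the lagged wind term is a
   candidate at all.
3. **What would a sparser program have seen?**  A useable-day record is cut
   into quarters/months (block lengths differing by ≤ 1 day); 1,000 seeded
   simulations draw one day per block and the averaged annual mean/min/max
   are compared with the raw record.

Sensor QC converts 15-minute sonde records to daily averages: internal gaps
are linearly interpolated, but a day is omitted whenever more than one
consecutive hour of raw data is missing (a 60-minute gap passes, 75 minutes
does not).

Because such monitoring records are rarely published, the package ships a
seeded synthetic-data generator (`chlorovar.synthetic`) that emulates the
relevant regimes — multiplicative seasonal structure with lognormal noise,
AR(1) wind with gusty maxima, Bernoulli–gamma rain, rain-driven salinity
drops, diel 15-minute structure — and records every planted bloom in a
ground-truth ledger, so every stage is testable against known truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate_fixtures.py
python analysis/03_decompose_timescales.py
```

prints (seed 7):

```
wrote 2-year scenario (seed 7) to .../results/fixtures
  chlorophyll: mean 70.2 > median 58.6 µg/L (right-skewed), range 14.0-410.2
  temperature: 8.9-30.9 °C
  ...
59 monthly grabs over 5 years (one month skipped) -> .../results/decomposition
  grand mean: 55.6 µg/L
  variability partition (SD of each timescale component):
    1. residual  0.431
    2. seasonal  0.309
    3. annual    0.245
```

The residual (sub-monthly) component dominates: most chlorophyll
variability in this regime happens between monthly samples.  Continuing,

```bash
python analysis/04_detect_blooms.py      # 13 merged events from 211 triggers
python analysis/05_fit_driver_models.py  # per-event AICc model selection
python analysis/06_sampling_frequency.py # quarterly/monthly resampling
```

In the driver table, 6 of 13 events admit a significant model and 5 of the
6 selected terms are wind-related (`wind_avg`, `wind_avg_lag1`, `wind_max`)
with positive coefficients — the generator plants wind-triggered blooms, and
the selection pipeline recovers that.  The sampling-frequency table shows
quarterly sampling under-reporting the annual maximum by ~60 % on this
spiky record while the annual mean is nearly unbiased.

The same stages are available as a CLI for real CSV records
(`chlorovar qc|decompose|detect|drivers|subsample|simulate`, each with
`--config`/`--seed`); see `chlorovar --help`.

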