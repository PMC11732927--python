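# Methods

## Problem setting

An emergency department (ED) is partitioned into three operational
sections — medical (36 beds), surgical (23), critical/resuscitation (6) —
plus the combined *bedoccupying* series (65 beds). The occupancy ratio
EDOR(s, t) = patients present ÷ capacity can exceed 1. A calendar day is a
**crisis day** for a section when EDOR ≥ 0.90 for at least 3 of its 24
hours; sustained occupancy at that level has been associated with excess
short-term mortality. The forecasting task is binary: at each morning
origin hour (8 a.m.–1 p.m.), predict whether the current day will be a
crisis day, per section. Bedoccupying, medical and surgical are forecast
targets; the critical series is too small to evaluate stably and enters
only as an explanatory variable.

The threshold comparison is `>=` (an EDOR of exactly 0.90 counts as
crowded) and the daily label covers the whole calendar day, not just the
hours after the origin. Both choices are configurable
(`CrowdingConfig`); operationally the distinction is minor because
crowding is essentially absent before 11 a.m. in both the motivating
setting and the shipped generator.

## Synthetic panel generator

Real sectioned ED occupancy is not redistributable, so the package ships a
generator whose output has the statistical structure the analysis relies
on. Occupancy is an M(t)/G/∞ queue per section: hourly arrival counts are
Poisson with intensity

    λ_s(t) = base_s · hour_mult_s(hour) · weekday_mult(weekday)
             · season(t) · dayfactor(day)

and each arrival stays `1 + NegBin(r, p)` whole hours (dispersion r = 1
gives the geometric law; means 6/5/3 h for medical/surgical/critical).
Occupancy counts patients present; **bedoccupying is defined as the sum of
the three sections** — a simulator convention, not a claim about any real
ED, where boarding patients may be counted differently.

Parameters and defaults:

- `base_s` (mean hourly arrivals at multiplier 1): 3.6554 medical, 2.2708
  surgical, 0.5743 critical. These were calibrated once, by bisection
  against the generator itself, so that long-run daily crisis prevalence
  sits near 28% (bedoccupying), 36% (medical), 25% (surgical) and ~10%
  (critical) — the descriptive regime the analysis assumes — and then
  frozen.
- `hour_mult_s`: a 24-vector with a deep overnight/early-morning trough
  and a late-morning arrival peak. Occupancy lags arrivals by roughly the
  mean length of stay, so simulated crowding peaks at 15–17 h and is
  ≤ 1% of hours at 8–10 a.m., reproducing the protected morning window
  that makes a morning forecast non-trivial. Surgical peaks slightly
  later than medical; critical has the deepest morning trough because
  with 6 beds its crowding probability is extremely sensitive to morning
  census.
- `weekday_mult`: (1.05, 1.05, 1.04, 1.03, 1.00, 0.86, 0.88) Mon–Sun —
  weekend crowding is rarer, not absent.
- `season`: ± 5% sinusoid peaking mid-January.
- `dayfactor`: a log-normal AR(1) daily demand shock shared by all
  sections (σ = 0.33, ρ = 0.45), capped at 1.7× so demand bursts saturate
  rather than flooding the protected morning trough. This shock is what
  makes the panel *forecastable from its own history*: it correlates the
  sections (so bedoccupying crises co-occur with section crises at a
  realistic rate) and it makes same-day morning occupancy genuinely
  informative about afternoon crowding, beyond what the calendar
  explains. Without it, lookback features would carry almost no signal
  and any history-vs-calendar ablation would be vacuous.

Covariates: daily temperatures follow an annual sinusoid with noise, with
min/max built as mean ∓ a positive half-range so the ordering
min ≤ mean ≤ max holds by construction; precipitation and snow depth use
the sentinel −1 on "none" days (a quirk of the source data the features
must tolerate); regional free-bed counts are a rounded AR(1) (mean 29,
persistence 0.8) explicitly allowed to go negative, as staff-reported
availability systems do. Holidays are a plain date list; the shipped
default covers Finnish-style fixed and Easter-relative holidays. Time is
naive local time, exactly 24 h per day, no DST.

What the generator does **not** emulate: patient-level structure (acuity,
diagnoses, arrival batching from incidents), closure/diversion episodes,
regime changes (strikes, epidemics), and any real cross-correlation
between weather and demand — weather here is pure nuisance covariate.
Passing tests therefore demonstrate that the *pipeline machinery* is
correct and that the protocol detects signal where signal exists; they do
not certify real-data performance.

## Design matrix

One row per (date, subgroup, origin); subgroups are integer-coded
(bedoccupying 0, critical 1, medical 2, surgical 3), origins are
8–13. Columns, in a fixed canonical order recorded in `schema.json`:
three holiday flags, weekday, month, beds_all, eight daily-label lags
(every subgroup at t−7 and t−14 — the weekly cycle at matched weekdays),
five weather values, subgroup, origin, the label, and the lookback block:
per subgroup, 168 hourly crowding indicators and 168 occupancy counts for
hours [origin−168, origin−1]. That is 22 + 1,344 = 1,366 columns; a
790-day panel gives 18,960 rows, with t−7 lags populated on 18,792 rows
and t−14 on 18,624.

The lookback window ends at origin−1 *by construction*, so rows at
different origins differ and same-hour leakage is impossible; `leakage_audit`
re-derives every populated lookback cell from the panel and also flags any
feature column that reproduces the label verbatim. Missing history (first
7/14 days for the lags, first week for the lookback) is kept as NaN with
rows retained — the learner treats missingness natively, and dropping rows
would silently change the evaluation span.

## Forecaster

A single LightGBM binary classifier serves all subgroups and origins;
subgroup and origin are categorical features, so the model can specialise
per section while sharing structure. Hyperparameters are the library
defaults (100 trees, 31 leaves, learning rate 0.1) plus a fixed seed,
`deterministic=True` and one thread — the package deliberately ships no
tuning, since reproducibility of the protocol, not leaderboard accuracy,
is the point; every parameter is overridable per run. No class
reweighting by default (metrics are reported at the 0.5 threshold);
a weight option can be passed through the hyperparameter dict.

Retraining follows the expanding window: the initial window is the first
365 days; for each test day the model refits on all rows dated strictly
before it and predicts that day's 24 rows. `retrain_stride_days` groups
several test days per refit so the 400+-refit reference protocol can be
scaled to a desk machine; stride 1 reproduces it exactly. A training
window containing a single class yields a constant-probability fallback
with a logged warning rather than a crash (relevant only for tiny
windows).

## Evaluation

Confusion-count metrics use prediction = (probability ≥ threshold); zero
denominators propagate NaN, never a silent 0. AUROC is the Mann–Whitney
statistic (ties half-credit); AUPRC is step-wise average precision, not
interpolated; both delegate to scikit-learn and both are pinned in tests
to hand-written brute-force oracles (exhaustive pair counting; exhaustive
threshold sweep). Confidence intervals are percentile bootstrap over
prediction rows within each (subgroup, origin) cell — the resampling unit
is the (day, subgroup, origin) pair — with 200 resamples at α = 0.05;
resamples that lose a class are redrawn (capped). F1 intervals use the
same engine as AUROC/AUPRC (one resampling mechanism for every metric;
the `ci_method` column records this). Inputs are canonically sorted
before resampling so intervals are row-order invariant at a fixed seed.
With ~10% cell prevalence and a test span of a few hundred days,
single-cell intervals are wide; this is a property of the design, not a
defect.

## Attribution

Shapley values come from the learner's built-in tree-exact algorithm
(`pred_contrib`), which computes the cover-weighted conditional-expectation
game exactly; tests verify it against direct subset enumeration of the
weighted-marginal formula on ≤ 8-feature models, along with local accuracy
(base value + Σφ equals the raw log-odds output on every row) and the
null-player property. The local surrogate is implemented in-package:
Gaussian/empirical perturbations around each instance, an exponential
proximity kernel on standardized distance (width 0.75·√d), and a ridge
fit on standardized coordinates; per-row importance is the absolute
coefficient. Global importance for both methods is the mean absolute
per-row attribution over a seeded subsample of evaluation rows (the
aggregation is a package choice; the subsample size and seed are recorded
in outputs). Lookback columns are ranked individually by default.

## Orchestration and reproducibility

The pipeline driver runs the six stages strictly through serialized
intermediates (CSV everywhere; the design matrix as Parquet with an
optional CSV flag, since a 18,960 × 1,366 CSV is ~180 MB), so any stage
can be inspected or re-run in isolation. One global seed fans out to
per-stage seeds via `SeedSequence.spawn`; the manifest records the config
hash, the derived seeds and a checksum per output file, and identical
configs yield identical checksums end to end.

## Problem sizes used by the shipped checks

The test suite exercises the full 790-day geometry (matrix build ≈ 1 s)
but runs forecasting checks at reduced spans and strides chosen as
sensible desk-scale defaults: 150–300-day panels, 7–50-day strides, and a
200-day panel with stride 7 for the protocol-integrity check. The
acceptance script runs the complete 790-day analysis with a 30-day refit
stride. Stride only changes refit frequency, not the temporal-separation
guarantees, which are asserted on every run.

## Known limitations

- The crisis definition ignores crowding duration beyond the 3-hour gate;
  an 8-hour crisis counts the same as a 3-hour one.
- Bedoccupying = section sum is a simulator identity that need not hold
  in a real ED.
- Synthetic performance levels (AUROC ≈ 0.8 at mid-morning origins) are
  properties of the generator's signal-to-noise choices and must not be
  read as expected real-data performance.
- The bootstrap treats rows within a cell as exchangeable; day-level
  serial dependence is not resampled in blocks.
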