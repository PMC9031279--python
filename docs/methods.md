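# Methods

`sitfield` implements the quantitative backbone of a sterile-insect-technique
(SIT) suppression trial against *Drosophila suzukii*: estimating how long
released sterile males survive in the field, how many are standing in the
crop on any day, how large the wild population is relative to them, and how
strongly the wild female population is suppressed compared with untreated
control sites.

## Survival from mark–release–recapture (MRR)

A cohort of ~5,000 colour-marked sterile males is released once; traps are
serviced daily for a 14-day horizon. Under a constant probability of daily
survival (PDS), expected daily recaptures decline geometrically, so the
ordinary-least-squares slope of log10(recaptures) on trapping day estimates
log10(PDS). Three corrections/conventions matter:

1. **Removal adjustment.** Trapping removes marked flies, which would
   otherwise be mis-read as mortality. Each day's count is multiplied by
   `R / (R − captures on previous days)`, where `R` is the release size.
   The denominator counts flies uncaptured *at the start of* the day, so
   day 1 carries a factor of exactly 1 and the adjustment is the identity on
   an all-zero series. The adjustment is exact only in expectation for small
   capture probabilities: at a per-day capture probability of 0.02 the
   residual slope bias is below 0.01 on the log10 scale (PDS bias < 0.02),
   which simulation-recovery tests confirm is well inside the ±0.05 band.
2. **Smoothing.** A centred three-day moving average with endpoint
   truncation (no padding). A centred window does not bias the slope; on an
   exactly geometric series it multiplies every value by the same constant,
   leaving the fitted slope untouched — this is the basis of the
   machine-precision oracle test.
3. **Zero handling.** Days whose smoothed value is zero are dropped from the
   regression rather than imputed with a pseudo-count; pseudo-counts bend
   the slope and there is no principled constant to use. At least three
   positive values must remain.

The slope's two-sided t test against zero (α = 0.05, exposed as a parameter)
screens replicates: only cohorts with a significantly negative slope enter
the aggregate, which reports the arithmetic mean and sample SD (n−1) of
slope, PDS, half-life `HL = ln 0.5 / ln PDS` and average life expectancy
`ALE = −1 / ln PDS` across replicates.

## Standing crop and wild abundance

The daily sterile standing crop follows the recursion
`SS[d] = SS[d−1] × PDS + R[d]` from the first release day, with `R[d] = 0`
on non-release days. Trap removals are ignored — over a season they are a
low single-digit percentage of releases and the recursion carries no removal
term. Two consequences are used as exact checks: with PDS = 1 the series
equals cumulative releases, and under constant daily release *r* it
converges to `r / (1 − PDS)` with a transient of `PDS^d` (≈1.5×10⁻⁶ of the
asymptote at day 60 for PDS 0.8).

Weekly wild-male abundance uses the ratio estimator
`SW = (W / S) × SS̄`, where `W` and `S` are wild and sterile males trapped
that ISO week and `SS̄` is the weekly mean of the daily standing crop
(averaged over all seven calendar days). The estimator assumes equal
capturability of wild and sterile males. Weeks with `S = 0` leave SW
undefined (reported missing), and the sterile:wild ratio is likewise missing
when `W = 0`. By default the standing crop feeding SW uses crop releases
only — wild abundance is estimated under the polytunnels, where perimeter
releases are not at comparable risk of capture — with an `"all"` scope
switch.

## Suppression metrics

The unit of wild pressure is total wild females per sticky trap per week:
collections within an ISO week are summed per trap (so twice-weekly
collections become weekly totals — summation preserves totals, which
averaging would not), then the mean and SE are taken across the site's
included traps. Traps with no record in a week contribute zero, since a
serviced-but-empty trap and an absent record are indistinguishable in count
data. Because weekly counts are volatile, suppression is computed on
three-week moving averages:

    suppression% = 100 × (1 − treated_MA / control_MA)

against each control site separately (controls differ; pooling hides that).
The MA is centred by default with a `trailing` option, matching the 3-day
MA convention in the survival module. Negative suppression is reported, not
clipped. No GLMM-style inference is attempted — the module reports means,
SEs and the suppression ratio only.

## Sterility assays

Fecundity is eggs per female per 24 h, normalising longer laying windows
through `laying_hours`; females that laid nothing stay in the denominator.
Fertility is the percentage of eggs developing to pupae; vials with no eggs
are excluded (they carry no information about egg viability). Group
fertility is reported both pooled (Σpupae/Σeggs) and as a mean ± SD of
per-record fertilities; the pooled value equals the egg-weighted mean of
per-record values, an identity under test. Induced sterility is
`100 × (1 − treated fertility / control fertility)`.

## Synthetic trial generator

The simulator produces release logs, trap logs and ground truth so every
estimator has a recoverable target.

* **Sterile males**: per-day Bernoulli survival at `pds_true` then Bernoulli
  capture at `capture_prob` for live, uncaptured flies, implemented as
  cohort-level binomial thinning (distributionally identical to per-fly
  simulation, which serves as the independent oracle in tests). Captured
  flies are removed.
* **Wild population**: zero until a seed week, then deterministic
  exponential growth per week; daily site-total captures are Poisson with
  mean `population × capture_prob`, split uniformly across traps. No
  published generative model for the wild population exists, so the
  exponential form and its rate are free emulator parameters, not estimates.
* **Traps**: uniform multinomial allocation; no spatial structure. A
  configurable number of traps is flagged excluded-from-analysis to
  exercise the auditability path.

Default configuration (the emulated study conditions): twice-weekly
(Tue/Fri) releases ramping linearly from 9,000 to 60,000 males/week over ISO
weeks 15–41 of 2021, 70% under the crop and 30% on the perimeter, rounded to
whole 100-male vials (season total ≈ 951,000); `pds_true = 0.80`;
`capture_prob = 0.02` per fly per day (≈7% of a cohort recaptured over its
lifetime); 33 treated-site traps with 2 excluded; wild population seeded at
50 in week 27, growing ×1.35/week at the treated site and ×1.5/week at the
two 6-trap control sites (chosen to reproduce the flat-then-exponential
late-season wild curve and a positive suppression signal; the treated/control
growth gap is a free parameter). Four dedicated longevity cohorts of 5,000
are released in the first four weeks, each with its own marker label so its
14-day recapture window is uncontaminated — bulk releases share a single
"bulk" marker. All randomness flows from one seeded generator; identical
seeds give byte-identical CSVs.

What the generator does **not** emulate: spatial dispersal and trap-distance
effects, weather-driven survival variation, sterile–wild mating competition
feeding back into wild growth, lure-efficiency drift, and operational
irregularities (missed collections, damaged traps). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
generative assumptions, not robustness to every feature of real field data.

## Numerical and design choices

* Week binning is ISO-8601 throughout; week indices are monotone within an
  ISO year (the first days of January may belong to the previous ISO year).
* Cohort day 1 is the release day itself — flies are at risk of capture from
  the moment of release.
* Survival fits use `scipy.stats.linregress`; a simple linear regression
  with a t test is the entire inferential content needed.
* Aggregates use sample SD (ddof = 1); a single replicate reports SD as nan.
* Undefined ratios (S = 0 or W = 0 weeks, zero control MA) are encoded as
  NaN/missing, never as zero or infinity, and JSON output renders them as
  null.
* Test problem sizes (8-week seasons, 8-trap sites, 20-cohort recovery runs)
  are chosen so the full suite completes in seconds while keeping Monte-Carlo
  standard errors small enough for 2-SE comparisons.

## Known limitations

* The removal adjustment's small-capture-probability bias (above) is
  accepted rather than corrected; an exact likelihood treatment of removal
  sampling is out of scope.
* The ratio estimator SW inherits any differential capturability between
  wild and sterile males one-for-one; no confidence intervals are produced
  for it.
* Excluded traps still physically remove marked flies in the simulator, so
  log-derived release-size bookkeeping is approximate at the fraction of
  captures landing on excluded traps (~6% of traps by default).
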