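# Methods

This note records the statistical model behind each pipeline stage, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## The synthetic survey sample

The generator emulates a stratified single-cluster sample of hospital EDs:
`n_strata` strata each contribute `clusters_per_stratum` sampled hospitals;
every visit at a sampled hospital is included with weight
`1/sampling_fraction` (default 0.2, weight 5). Cluster sizes are Poisson
with mean `visits_per_cluster_mean`. Trauma-center status is a hospital-level
indicator (default probability 0.30); census region cycles over strata.
Visit-level covariates are drawn independently: year uniform over 2006–2012,
age from a 20-point distribution (default uniform over 0–19), sex with
P(female) = 0.40.

Mechanism, severity, and TBI follow the published national profile wherever
a value is printed:

- `mechanism_mix` defaults to pedestrian 0.08 / bicyclist 0.03 /
  other-injury 0.30 / non-injury 0.59. The pedestrian:bicyclist ratio within
  the cohort (72.7 : 27.3) matches the published share; the cohort's share
  of *all* visits is deliberately inflated from the real 0.21% to 11% so
  that test-scale datasets (10⁴–10⁵ visits) contain a workable cohort. This
  is a scale-down of the non-cohort background, not a claim about real ED
  volumes; estimates *within* the cohort are unaffected.
- `severity_model` (probability of severe injury by mechanism): 0.095
  pedestrian / 0.092 bicyclist (the published per-10⁴ severe rates 946.0 and
  919.5), 0.02 other-injury, 0.005 non-injury.
- `tbi_model` (TBI-type distribution by mechanism): total TBI prevalence
  6.3% of pedestrian and 7.6% of bicyclist injuries, split 26/67/7 across
  Types I/II/III per the published grade table.
- The latent severity indicator drives both the fatality model and the
  diagnosis-code pools (severe records carry torso internal-organ codes in
  addition to their primary code), so that SRRs estimated downstream assign
  low survival ratios to the codes that co-occur with deaths. The empirical
  ICISS < 0.94 indicator therefore correlates with, but does not exactly
  reproduce, the latent indicator; estimator tests that isolate the
  regression machinery use the latent column (`gt_severe`).

Fatality has two modes. The `logistic` mode mirrors the downstream model:
log-odds terms default to the published adjusted odds ratios (age ln 0.7,
female ln 0.9, severe ln 16.9, trauma center ln 0.9, pedestrian ln 2.4, TBI
ln 6.3) plus a positive interaction ln 2.0. The intercept (−4.94) was set by
exhaustive enumeration over the covariate grid so the implied cohort case
fatality is ≈73 per 10⁴ visits, on the scale of the published 73.7–83.7
endpoints. The `risk_additive` mode specifies death probability directly as
`r_base + risk_ped·ped + risk_tbi·tbi + risk_interaction·ped·tbi` (clipped
to [0, 1]); on this scale the interaction contrast equals
`risk_interaction` by construction, which makes additive-interaction ground
truth exactly specifiable — the natural scale for a method that tests
departures from risk additivity.

`true_risks` marginalizes the fatality model over the configured covariate
distribution by exhaustive enumeration of the discrete grid (20 ages × 2 ×
2 × 2), giving the population risks in the four {pedestrian, TBI} cells —
the oracle for the interaction stage. "Pedestrian−" denotes the bicyclist
arm, matching the cohort contrast.

What the generator does **not** emulate: post-stratification weight
adjustments (weights are constant), between-hospital case-mix heterogeneity
beyond the trauma-center indicator, within-record code correlations beyond
the severity pools, repeat visits by the same patient, and real ICD coding
noise. Passing tests therefore demonstrate correctness of the estimators
under the declared design, not robustness to the messiness of real
administrative data.

## Cohort rules

E-codes classify through a packaged CSV (`ecode_classes.csv`): traffic codes
E810–E819 with fourth digit 7 (pedestrian) or 6 (pedal cyclist), the
non-traffic block E820–E825 with the same person digits, E826.0 (pedestrian
struck by a bicyclist), with exclusions E814.0–.4 and E826.1–.4/.8–.9. A
visit is included iff any of its ≤4 E-codes qualifies and none excludes; the
first qualifying code in listed order sets the mechanism. Because every code
maps to exactly one category, a true tie cannot occur; the first-listed rule
is the deterministic resolution when a record carries both pedestrian and
bicyclist codes. Whether non-traffic codes belong in the cohort is not
settled in the published record; they are included by default and the
extraction summary reports with/without-non-traffic sensitivity counts.

## ICISS

SRRs are estimated unweighted over *all* visits (not just the cohort),
following the original formulation of the score; codes with fewer than
`min_count` (default 10) occurrences are omitted rather than estimated from
a handful of visits, since singleton 0/1 ratios dominate products. No
shrinkage is applied (a documented extension point). Scoring multiplies the
SRRs of the first ten listed codes; codes without an entry are skipped and
the result flagged incomplete. The severity cut is strict: severe ⇔
probability < 0.94. An externally estimated SRR table can be supplied in
place of the in-sample estimate.

## Barell / TBI

Lookup is at full code precision against packaged CSVs covering the complete
ICD-9 TBI block (800–801, 803–804 with LOC fifth digits, 850–854, 950.1–.3,
995.55) plus the synthetic vocabulary; a code that requires a fifth digit
but arrives with four is unmappable, reproducing the missingness mechanism
of real discharge data (the generator can emit truncated codes via
`p_truncated_tbi`). The model's TBI indicator comes from the first-listed
(primary) diagnosis; an any-position flag is also computed because the
published "implicated in fatalities" figure is ambiguous between the two
bases. Full 36×12 matrix coverage is an extension point — the analysis needs
the TBI rows, extremity rows, head/face/neck and torso only.

## Survey estimation

Totals use the with-replacement first-stage approximation,
Var = Σ_h n_h/(n_h−1) Σ_i (t_hi − t̄_h)² over weighted cluster totals, with
domain membership handled by zero contribution. A Monte-Carlo property test
verifies this estimator is unbiased for the variance of the weighted total
under with-replacement cluster sampling. Strata with a single sampled
cluster are treated as certainty units (zero contribution, warning) so
small designs remain usable. Normal-theory 95% intervals (±1.96·SE) apply
to totals; ratio and percent-change uncertainty uses the simulation method —
1000 independent normal draws around each estimate by default, median point
estimate, 2.5/97.5-percentile interval, with non-positive denominator draws
rejected, resampled and counted. Percent change is (a−b)/a·100 with `a` the
earlier period, so a decline is positive. Trends are OLS of the annual rate
series on calendar year with a t-test on the slope.

## Fatality model

IRLS with tolerance 1e-10 and at most 100 iterations; the variance is a
sandwich whose score contributions are summed to the hospital level and
centered within strata with the n_h/(n_h−1) factor. Stratum fixed effects
are *not* entered as covariates — the design enters through the variance
only, as in design-adjusted analyses of single-stage cluster samples.
Without cluster information the estimator reduces exactly to HC0, which is
the cross-check against the independent GLM oracle. Zero-variance columns
(e.g. the female indicator in an all-male cohort) are dropped with a
warning; a linear predictor exceeding ±30 flags likely quasi-separation and
marks the fit not converged. Year adjustment, when enabled, uses
calendar-year indicators against the earliest year; the published analysis
names only "an approach recommended for year-to-year survey variability",
and indicators are the transparent realization. Constant rescaling of all
weights provably leaves both coefficients and the sandwich unchanged, and a
test asserts it.

## Additive interaction

Cell risks are weighted deaths over weighted records per
{pedestrian, bicyclist} × {TBI, no-TBI} cell at a configurable scale
(default per 100,000 discharges); IC and AP follow by exact arithmetic, and
AP is scale-invariant. The bootstrap resamples hospitals with replacement
within strata (n_h draws, weights rescaled by n_h/(n_h−1)), recomputing the
quartet per replicate; replicates with an empty cell are dropped and
counted, and more than 50% dropped aborts. Both the plug-in values and the
replicate means are reported — on real data the two can differ (a published
bootstrap AP of 49.1% against a 51.7% plug-in), and conflating them hides
skew in the replicate distribution. Rate-scale variants on the odds-ratio
scale (RERI, synergy index) are out of scope.

## Numerical and reproducibility choices

All randomness flows from named integer seeds (generator, simulation,
bootstrap) recorded in the pipeline manifest; identical configuration
yields a byte-identical report bundle (CSV floats written at %.10g, JSON
with sorted keys). Rendered reports round rates and percentages to one
decimal and odds ratios to two significant figures; CSV/JSON outputs carry
full precision. Degenerate inputs have defined behavior throughout: empty
diagnosis lists score as undefined rather than 1.0, empty domains give a
zero total with zero SE, an all-survivor dataset yields unit SRRs and no
severe records, and a single-class outcome is a hard error rather than a
degenerate fit.

## Problem sizes in the test suite

Statistical checks run at deliberately modest sizes chosen for estimator
validity rather than realism: coverage checks use 30–50 seeded replicates of
~15,000-visit samples with 100 clusters (percentile cluster-bootstrap
intervals need on the order of a hundred clusters to hold their nominal
level), parameter recovery uses a single ~10⁵-visit run, and the Monte-Carlo
variance-unbiasedness check uses 4,000 resamples of a five-cluster toy
stratum. The demo pipeline generates ~1.3 × 10⁵ visits.

## Known limitations

- SRRs are estimated on the same synthetic sample they score
  (an external-table path exists but no reference table is shipped).
- The Barell asset covers the TBI block and the synthetic vocabulary, not
  all 36 body regions.
- The generator's clusters are exchangeable within strata; designs with
  informative cluster sizes or weights are not represented.
- The fatality model assumes a correctly specified logistic link when the
  generator runs in risk-additive mode; this mismatch is intentional (it is
  what the additive-interaction machinery is for) but means the logistic
  coefficients have no ground truth in that mode.
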