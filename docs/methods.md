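# Methods

## The interpretation model

The engine interprets a single pre/post-bronchodilator spirometry using the
fixed-ratio convention: FEV1/FVC < 0.70 signals airflow obstruction and a
percent-of-predicted below 80 marks a reduced FVC or FEV1. Pattern and
severity are decided from *pre*-bronchodilator values — patterns are defined
on the obtained basal values against the reference values — while the
post-bronchodilator pair feeds only the reversibility test. All comparisons
are made at full floating-point precision; rounding happens only at display
time (percents to 1 decimal).

The published four-pattern definitions leave two regions of index space
uncovered, which a total classifier must resolve:

* **FVC% exactly 80 with a reduced ratio.** The obstructive definition uses
  "FVC% > 80" while normal uses "≥ 80". We treat FVC% ≥ 80 as "not reduced"
  in every branch — one coherent half-open partition — and emit the
  `BOUNDARY_FVC_80` audit flag whenever equality occurs.
* **Preserved ratio and FVC% with FEV1% < 80** (the "non-specific"
  reduction). Neither the obstructive (ratio preserved) nor the restrictive
  (FVC preserved) criterion is met; we classify normal and emit
  `NONSPECIFIC_LOW_FEV1` so the information is not lost.

A third flag, `MIXED_FEV1_NOT_REDUCED`, marks mixed-pattern records whose
FEV1% is nevertheless ≥ 80 (the definition expects it reduced).

Severity bands are half-open with each printed integer edge belonging to
the milder band: mild [70, ∞), moderate [60, 70), moderately severe
[50, 60), severe [35, 50), very severe [0, 35). The printed band wording
("moderate 60–69%") leaves non-integer percents between 69 and 70
unassigned; the half-open convention preserves the printed integer anchors
while partitioning the whole line. The grading index follows the SEPAR /
ATS-ERS convention: FEV1% for obstructive patterns, FVC% for spirometric
restriction. Which index a mixed pattern should use is not fixed by the
published definitions; we grade mixed on FEV1%, consistent with its
obstructive component, and record the index used in every report.

The bronchodilator test is positive when either FEV1 or FVC improves by at
least 12% of its pre-bronchodilator value *and* at least 0.2 L (the
conjunction applies per index, the disjunction across indices); an
improvement short of that is "not significant", and no improvement is
"negative/unmodified". The percent denominator is the pre-bronchodilator
value. Records lacking both post values are "not evaluable"; exactly one
missing post value is rejected as invalid rather than guessed at. A
three-level outcome scheme is used, collapsing "negative" and "not
modified" into one level.

The 0.70 ratio cut-off is known to over-call obstruction in older and
under-call it in younger subjects relative to age-dependent lower limits of
normal; LLN-based classification is out of scope (no reference-equation
coefficients ship with the package), but the threshold — like the 80%
threshold, severity edges and bronchodilator criteria — is a configurable
`Thresholds` field. Predicted values are caller-supplied inputs; a
`ReferencePredictor` callable can be registered to fill them from
anthropometrics, and none is shipped.

## Diagnostic accuracy

Patterns are dichotomized (obstructive, restriction, mixed → impaired) and
tallied into a 2×2 confusion table against the gold-standard rater.
Confidence intervals follow the methods that reproduce the published
validity table of the reference study:

* sensitivity, specificity, accuracy — exact Clopper–Pearson (inverted
  binomial tails, computed via the beta quantile form);
* PPV and NPV — standard logit intervals with the variance propagated from
  the binomial errors of sensitivity and specificity (Mercaldo et al.
  2007). At a degenerate predictive value (0% or 100%) the logit is
  undefined; the bound away from the boundary then comes from the Wilson
  score interval with continuity correction, which reproduces the reference
  study's printed interval for a 100% NPV;
* likelihood ratios — the log method (normal interval on the log scale);
  +LR is reported as infinite with an open interval when there are no false
  positives, and −LR as exactly 0 with no interval when there are no false
  negatives;
* AUC — the single-threshold ROC has one interior operating point, so the
  trapezoidal area is (sens + spec)/2; its CI is Hanley–McNeil.

Percent displays round to 1 decimal but never show an inexact value as
exactly 100 or 0 (99.97% displays as 99.9), matching how such tables are
conventionally printed.

The Wald planning formula n = ⌈z²·p(1−p)/d²⌉ is provided for CI-precision
sample-size reasoning. Note that for p = 0.90 and d = 0.07 it gives n = 71;
the reference study reports using 45 impaired cases for that precision,
which the standard formula does not reproduce. The formula is implemented
as standard and the discrepancy left as-is.

## Agreement

Cohen's kappa is computed from the k×k contingency table:
κ = (p_o − p_e)/(1 − p_e) with p_o the diagonal fraction and p_e the
product-marginal chance agreement. The standard error is the
Fleiss–Cohen–Everitt asymptotic formula for a non-null kappa, and the CI is
the symmetric Wald interval κ ± z·SE, deliberately uncapped above 1 — the
reference study prints upper bounds such as 1.017. The study does not name
its SE formula; Fleiss–Cohen–Everitt reproduces every printed interval to
within ±0.01, and point estimates are reproduced to 3 decimals.

Supporting operations: `merge_categories` folds categories (e.g. mixed into
obstructive, as done when one rater does not separate them) by summing rows
and columns, preserving the total; `pool_severity` maps the five grades to
three groups (mild / moderate–moderately severe / severe–very severe), with
`not_applicable` excluded by an explicit signal; `intra_rater` cross-
tabulates first against blinded repeat calls; incomplete pairs (a rater who
made no call) are dropped pairwise, matching the varying per-column n of
agreement tables. Category order is fixed as (normal, obstructive,
spirometric_restriction, mixed) for reproducible layouts.

## Synthetic data

The generator emulates the composition of the validation study: default
pattern prevalence (0.64, 0.12, 0.12, 0.12) for (normal, obstructive,
restriction, mixed) — about 64% normal with at least 10% of each impaired
pattern, as the study's blocks were composed — a severity mix weighted
toward mild/moderate disease (0.35/0.25/0.20/0.15/0.05 from mild to very
severe) as seen in primary-care smokers' cohorts, and a 15% bronchodilator-
positive rate, a typical minority in such populations. Remaining records
split evenly between sub-significant improvement and no change.

Sampling works backwards from the classifier: a target pattern (and grade)
is drawn first, then FVC%, FEV1% and the ratio are drawn uniformly inside
that pattern's decision region at least `boundary_margin` (default 1
percent point; margin/100 on the ratio) away from every threshold, and
litres are back-computed from a predicted FVC drawn uniformly within broad
sex-specific physiologic ranges (FEV1's predicted value is derived, not
independently sampled). With a positive margin the generator is an exact
inverse image of the classifier's partition, so round-trip label recovery
is exact by construction — that is what makes it a useful end-to-end
oracle. Margins ≥ 5 make some severity band empty and raise
`GenerationError`.

What the generator does **not** emulate: correlated biological noise,
measurement error, GLI-style covariate-dependent reference values, quality
failures, or borderline cases near thresholds (it excludes them by
design). Passing round-trip tests therefore demonstrates the internal
consistency of generator and engine, not field performance on real
spirometries; the accuracy and agreement statistics against the embedded
study tables are what tie the package to observed data.

Simulated raters draw each call from a row-stochastic confusion matrix
given the true pattern, with an independent omission probability; the
closed-form kappa of such a rater against truth
(p_o = Σ_t π_t C_tt, p_e = Σ_j π_j (πᵀC)_j) anchors the Monte-Carlo
recovery tests.

The published cross-tabulations (two 2×2 normal/impaired tables, a 3×3 and
a 4×4 pattern table, n = 118 each) are embedded as integer count fixtures;
the record-level data behind them were never published, so record-level
synthesis is openly parameterized rather than imitating the original
subjects.

## Numerical and testing choices

* Problem sizes: property suites use a ~10⁴-point threshold-spanning grid,
  exhaustive two-category label lists to length 5, a 10⁵-record engine
  -vs-flat-chain-oracle comparison, 10⁴-record round-trips and 10⁵-rep
  parametric bootstraps — all seeded and chosen to keep the default test
  run fast while leaving Monte-Carlo error well below the tolerances
  tested.
* Confidence level enters every interval through the normal (or beta)
  quantile at the requested level; 0.95 throughout unless configured.
* The kappa oracle in tests recomputes p_o/p_e directly from raw label
  lists, and scikit-learn's `cohen_kappa_score` serves as an independent
  cross-check of the point estimate; neither is used in the
  implementation.
* Known limitations: no weighted or multi-rater kappa; no multi-threshold
  ROC; no prevalence-adjusted predictive values; no spirometry quality
  grading; bronchodilator-test concordance between raters is out of scope
  (the reference study could not compute it).
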