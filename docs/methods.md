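# Methods

This note documents the statistical model behind the package, the
conventions and defaults it fixes, what the synthetic cohorts do and do not
emulate, and the design decisions taken where the layered rule's published
description left room.

## The layered rule

All thresholding uses one convention: **a score at or above a cutoff is
called positive**. With fused score `s = (t1wi + t2wi)/2`:

| group      | condition        | examination | final call        |
|------------|------------------|-------------|-------------------|
| positive   | `s ≥ c1`         | enhanced    | recurrent         |
| suspicious | `c2 ≤ s < c1`    | enhanced    | `t1wic ≥ c3`      |
| negative   | `s < c2`         | unenhanced  | recurrence-free   |

Two decisions here were genuinely open:

* **The positive group's call does not consult T1WIC.** The published
  worked-example arithmetic requires it: the layered rule's true positives
  equal the fused model's true positives plus the suspicious-group
  recoveries (internal: 166 + 12 = 178 of 197 = 90.36%), which only holds if
  positive-group calls are final. It also gives the rule its dominance
  property — layered calls are a superset of fused-only calls, so
  sensitivity can only rise and specificity only fall.
* **`c2` thresholds the fused score, not the T1WIC score.** A patient's
  T1WIC score cannot exist before the contrast scan that the referral
  decision grants; negatives never receive contrast. The alternative
  reading (thresholding non-positive patients' T1WIC scores) is available
  behind `select_secondary_cutoff(..., on="t1wic")` for exploration but is
  not the pipeline default.

## Cutoff selection

`c1` and `c3` are Youden cutoffs (`J = sens + spec − 1`) over the observed
scores; ties in `J` break toward the smallest maximising threshold, i.e.
toward sensitivity, which is the quantity surveillance protects. `c2` is the
largest candidate threshold (unique observed referral scores below `c1`,
plus 0) at which the whole rule's sensitivity stays at or above the floor
(default 0.90) — the fewest contrast referrals that honour the floor. When
the first level alone meets the floor the search reports that no referral
tier is needed (operationally `c2 = c1`, an empty suspicious group); when
even `c2 = 0` cannot reach it (no missed recurrence clears `c3`), it returns
0 with an explicit `floor_met = False` flag rather than silently degrading.
Feasibility is checked as `detections ≥ floor·n_pos − 1e-9`; the epsilon
absorbs float artifacts like `0.9 × 200 = 180.00000000000003`.

The published cutoffs (internal `c1 = 0.490`, `c2 = 0.197`; external
`c1 = 0.460`, `c2 = 0.282`) are carried as overrides, not re-derived: they
came from private score distributions, and the exact procedure that produced
the secondary values was not fully specified. The T1WIC cutoff `c3` was not
published at all, so it is a required configurable defaulting to the Youden
cutoff of the calibration data; the worked-example tables use 0.5.

## Diagnostic statistics

* **Wald CIs, z = 1.959964.** The published per-model diagnostic tables are
  reproduced cell-for-cell by the plain Wald interval
  `p̂ ± z√(p̂(1−p̂)/n)` clipped to [0, 1] (e.g. 166/197 → 79.18–89.35),
  which identifies the otherwise unstated method. Intervals are clipped
  before display; no table cell actually triggers the clip. The
  radiologist-reader rows' published intervals were computed some other,
  unstated way; the package reproduces their point estimates and makes no
  claim about those intervals.
* **Display rounding** is half-away-from-zero to two decimals for
  percentages, nearest unit for currency, one decimal for hours. Unrounded
  values are retained on every `MetricWithCI` (`raw`).
* **McNemar** compares per-patient correctness of two strategies:
  `Z = (|b−c| − k)/√(b+c)` signed by `b−c`, two-sided normal p, `k = 1`
  only when the continuity-correction flag is on (default off — the source
  analysis names only "McNemar's Z test", so both variants are exposed and
  the default documented). No discordant pairs ⇒ statistic 0, p = 1.
* **ROC/AUC**: curve over all unique thresholds (scikit-learn,
  `drop_intermediate=False`), AUC as the tie-corrected Mann–Whitney
  probability, which equals the trapezoidal curve area. AUC CIs and the
  paired AUC test use DeLong's placement components via midranks; the
  variance of a difference combines per-class component covariances. A
  degenerate variance with zero difference yields p = 1. Whether the source
  analysis used DeLong or bootstrap intervals is not stated; DeLong is this
  package's choice.
* **α = 0.05/3** by default for pairwise comparisons: Bonferroni over the
  three model pairs compared.

## Synthetic cohorts

`generate_cohort` draws labels Bernoulli(prevalence), then latent
`z_j = √ρ·u + √(1−ρ)·e_j + y·δ_j` per score (unit variance, pairwise latent
correlation ρ), with `δ_j = √2·Φ⁻¹(AUC_j)` so each latent hits its target
AUC exactly in expectation; scores are `logistic(z)` — strictly inside
(0, 1) and rank-equivalent to the latents, so the AUC calibration survives
squashing. Defaults mirror the internal evaluation cohort: n = 433,
prevalence 197/433 ≈ 0.455, AUC targets (0.9098, 0.9145, 0.9124). The
inter-score correlation is unobservable from published material; ρ = 0.5 is
a single fixed modelling choice representing "the models agree on easy
cases". A single-class label draw is retried up to 100 times, then fails
loudly.

What this emulates: class mix, per-model discrimination, correlated errors,
probability-like score support. What it does not: lesion geometry, image
features, score miscalibration, site effects, time-serial dependence between
visits. Passing simulation tests therefore validates the *pipeline
arithmetic and its statistical machinery* under the stated assumptions, not
clinical performance on real MRI.

## Economics

Group proportions scale to a hypothetical cohort (default 1,000) with
largest-remainder apportionment (group patients sum exactly to the cohort;
true/detected counts round to nearest and are clipped to nest). Enhanced
examinations: positive + suspicious groups under the layered rule, everyone
under the conventional and T1WIC-only strategies, no one under fused-only.
Unit prices/times default to the published whole-cohort totals divided by
1,000 — enhanced ￥2,444 / 0.2264 h, unenhanced ￥2,246 / 0.1292 h — because
per-examination prices were never printed; these derived units reproduce the
published time totals exactly and the cost totals to within ~0.003% (the
residual implies unprinted exact prices). The cost of one detection in a
group is the conventional whole-cohort cost divided by the group's detected
count (validated against all six published per-group figures); zero
detections price at infinity, rendered `"infinity"` in reports. Currency
converts at ￥7.17 per US$ (2024). Fees beyond the MR examination itself
(biopsy, treatment, repeat imaging) are out of scope.

One bookkeeping subtlety: the published hypothetical cohort credits the
negative group with 5 detections per 1,000 — detections made at *later*
follow-up, since negatives receive no contrast at the index examination.
The triage module reports negative-group recurrences as missed at the index
examination (detected = 0); the published negative-group detection counts
enter only as economics inputs when reproducing the published per-group
costs.

## Numerical and testing notes

* Score tables round-trip exactly: floats serialise as shortest-repr
  decimals.
* Youden and AUC implementations are checked against exhaustive O(n²)
  oracles on tied, random instances up to n = 500; DeLong variances against
  leave-one-out jackknives (15% relative band on 20-patient instances);
  McNemar against the χ² of statsmodels and a 1,000-replicate null
  simulation (level 0.05 ± 0.02).
* Simulation-based checks run at n = 20,000 (AUC calibration, ±0.01),
  n = 50,000 (prevalence concentration, ±0.01) and n = 200,000 (population
  oracles for cutoff/rate recovery); these sizes put Monte-Carlo error
  comfortably inside the asserted bands while keeping the suite fast. The
  empirical-Youden recovery tolerance of 0.05 on the score scale reflects
  the n^(−1/3) convergence rate of argmax-type estimators at n = 20,000.
* The pipeline bundle is a pure function of configuration and seed; the run
  log records a config hash and library versions, and excludes the output
  path so identical analyses in different directories are byte-identical.

## Known limitations

* The package consumes model *scores*; it neither trains nor runs the
  underlying image models, and no DICOM/image handling is included.
* Cutoffs transfer poorly across sites with different score distributions;
  the external worked example uses its own published cutoffs for exactly
  that reason. Calibrate per site.
* The economics model is an examination-cost model only — no downstream
  costs, discounting or health-state utilities — and inherits the small
  residual between published totals and derived unit prices noted above.
* Wald intervals undercover for proportions near 0 or 1 at small n; they
  are used here because they are what the reference tables used.
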