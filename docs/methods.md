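# Methods

## Problem and scope

`oncosep` operationalizes a retrospective sepsis-risk analysis for adult
patients with liver, lung or breast cancer who present to the emergency
room. The unit of analysis is the **ER visit**; all predictive information
comes from the observation window 2–7 days *before* the visit (inclusive on
both ends), so the task is early risk stratification, not bedside
detection. Visits with no usable in-window events are dropped; a patient may
contribute multiple visits, each its own row.

## Sepsis-3 labeling

A visit is *sepsis* when the SOFA total rises by ≥ 2 points within a
suspected-infection window — a bacterial culture with at least one
intravenous antibiotic administered within ±24 h of it (boundary
inclusive). The baseline is the last SOFA total strictly before the window;
an unmeasured baseline counts as 0, so a first ER visit with an in-window
total of ≥ 2 qualifies. When several windows qualify, the earliest is the
triggering window (the clinically conservative onset). SOFA is recomputed at
every timestamp carrying a new component value, with last observation
carried forward per component — the cadence of recomputation is a design
choice of this package, not a claim about any particular hospital's
practice.

The six-system threshold table (respiration PaO₂/FiO₂, coagulation
platelets, liver bilirubin, cardiovascular MAP/vasopressor, CNS GCS, renal
creatinine) ships as a versioned, unit-annotated YAML file
(`data/sofa_thresholds.yaml`) and is overridable. Three bedside details are
deliberately simplified and should be kept in mind when applying the labeler
to real data:

- respiration ignores ventilation status (thresholds 400/300/200/100 only);
- vasopressor dose tiers are collapsed to a presence flag scoring 2;
- the renal urine-output criterion is omitted.

Missing components score 0 and are flagged, never imputed.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes. Its
defaults are the study conditions:

- **Group sizes** 928 controls / 455 sepsis; repeat-visit probability 0.06
  (≈1.06 visits/patient).
- **Demographics** male fraction 0.528 (control) / 0.712 (sepsis); cancer
  mix (liver, lung, breast) = (.194, .574, .232) / (.308, .602, .090); age
  normal(58.2, 11.0) / normal(60.3, 11.0) clipped to 18–95 years; weight
  normal(63.7, 10.7) / normal(64.3, 11.3) kg. (The source cohort table
  prints a sepsis-age SD of 0.5 and a pooled weight SD of 0.9, inconsistent
  with every other ~11-scale entry; the ~11 scale is used.)
- **Lab panel** — eight tests with published per-group means/SDs: albumin,
  total protein, cholesterol, A/G ratio, APTT, PT(%), PT(INR), PT(sec).
  Values are drawn from a **moment-matched zero-truncated normal**: the
  underlying (μ₀, σ₀) are solved (Brent root-finding on the truncated cv) so
  the truncated distribution reproduces the target mean and SD exactly.
  Naive truncation of N(mean, sd) would inflate the A/G mean by ~0.18 — a
  visible bias at these parameters. A zero-truncated normal cannot attain a
  coefficient of variation ≥ 1, so labs printed with cv ≥ 0.95 (cholesterol
  1.05, APTT 1.40, PT% 1.27, PT-INR 1.29, PT-sec 1.25) use a moment-matched
  gamma instead — also nonnegative, also matching both moments. Each lab
  value is missing with probability 0.10 by default. Other lab types are
  user-configurable; no published per-group parameters exist for them in the
  running text, so none ship as defaults.
- **Prescriptions** — an abstract 18-drug catalog with per-group daily
  probabilities over the six window days, plus joint pair boosts that make
  the narcotic-analgesic pair (opioid alkaloids + synthetic narcotics)
  exceed support 0.05 only in the sepsis group (≈0.29 vs ≈0.02). Drugs are
  identifiers with frequencies, not pharmacology.
- **SOFA trajectories** — all patients get a normal-physiology baseline
  3 days before the visit. Sepsis-group visits get a culture shortly after
  arrival, an IV antibiotic within 24 h of it, and in-window measurements in
  the score-2 bands of several systems (guaranteed Δ ≥ 2). Controls get
  either no culture (70%) or a culture + antibiotic with stable physiology
  (Δ ≤ 1 up to rare noise). The labeler therefore recovers ground truth for
  ≥ 95% of visits by construction — this validates the labeling machinery,
  not the clinical rule.

What the generator does **not** emulate: correlated lab panels (labs are
drawn independently), temporal drift within the window, informative
missingness, coding noise in diagnoses, multi-morbidity, or real
prescription semantics. Passing tests therefore demonstrate pipeline
correctness on data satisfying the stated assumptions, not expected
performance on hospital data.

## Preprocessing

- Diagnosis codes: punctuation stripped, uppercased, truncated to
  3 characters (C22.0 → C22); codes shorter than 3 characters are rejected.
- Lab coverage: a lab type is kept iff measured in **strictly more than**
  60% of patients.
- Outliers: |x − median| > k·(1.4826·MAD) with k = 5 marks an entry
  missing. With zero MAD the robust z is infinite, so any deviation from the
  median is extreme; constant features are never trimmed.
- Imputation: mean of the (cancer type, sex, 5-year age bin) stratum, with a
  fallback cascade dropping age, then sex, then the global mean. Exact-age
  strata would be near-empty; 5 years keeps strata populated and is
  configurable. Imputation never drops rows.
- A user-supplied lab exclusion list handles leakage-prone tests (tests
  pathognomonic for one diagnosis group); none are excluded by default.

## Association mining and vectorization

Transactions are deduplicated same-day drug baskets per patient. FP-growth
is implemented in-package (prefix tree + conditional pattern bases); pair
support uses the basket count as N(s). Mining runs separately per recovered
group (never per generator ground truth); selection keeps pairs with
support ≥ 0.05. Graphs are unweighted and undirected; node size proxies
(degree, BFS average shortest path within the component, ∞ for isolated
nodes) rank drugs by co-prescription centrality. Itemsets larger than pairs
are mined but only pairs are graphed and vectorized, matching the pairwise
downstream use.

The drug set for vectorization is the **union** of the per-group
selections. Pair frequencies are distinct prescription days within the
window. The published algebra for the three pair summaries is not printed
legibly in the source; the forms used here — I = x·y, H = 2xy/(x+y) (0 when
x+y=0), T = arctan2(y, x) (0 at the origin) — are this package's
reconstruction of the verbal definitions ("level of interaction", "overall
intensity, sensitive", "geometric angle difference") and are injected
through a strategy hook so an alternative algebra can be swapped without
touching the pipeline. Useful identities: I scales quadratically and H
linearly under (x,y) → (cx,cy); T is scale-invariant and
T(x,y)+T(y,x) = π/2 for positive pairs.

## Lab screening

Per-lab two-sided Welch (unequal-variance) t-tests; identical degenerate
samples define t = 0, p = 1. Tier map: NS, * p<.05, ** p<.005, *** p<.001,
**** p<.0001 (the published tier list repeats ".001"; the second occurrence
is treated as .0001). Selection keeps labs at p < .001 per test,
uncorrected, matching the published per-test usage; Bonferroni is available
but off by default. At the published group sizes the seven large-effect labs
have rejection z ≥ 6 (power ≈ 1); total protein's effect is ≈3 SE and clears
.001 only intermittently. Screening operates per visit, matching the feature
table.

## Models and evaluation

Stratified 5-fold cross-validation, seeded; scaling is fit inside each
training fold. Threshold 0.5 binarizes scores for accuracy / precision /
recall / F1; AUROC is the rank statistic and AUPRC the step-integrated
precision-recall area. Aggregates are fold means (pooled-prediction metrics
are reported alongside). Grid search evaluates candidates by nested CV on
training data only, maximizing mean AUROC with ties to the first-listed
point.

Families: logistic regression and a 20-tree random forest (sklearn); a
feedforward net (sklearn MLP, 32-16 hidden); a residual CNN and an LSTM
implemented on the package's numpy autograd at smoke-test scale (4-channel
stem + one residual block + global average pooling; 8-unit LSTM), trained
with Adam on the logistic loss. The CNN consumes features zero-padded in
manifest order to a 42×42 image (capacity 1764 features — exceeding it is an
error; the padded positions are zeros, and the ordering is this package's
choice). The LSTM consumes (rows, time, features); true variable-length
event sequences are zero-padded to the cohort maximum, and a flat table
degenerates to a length-1 sequence. The deep families exercise the reshaping
conventions and the evaluation harness; they are not tuned, and their
gradients are verified against central finite differences in the tests.

Feature contributions use an exact path-dependent Tree-Shapley recursion
(per-tree EXTEND/UNWIND over the feature path, forest values averaged over
trees), verified against exhaustive coalition enumeration on toy trees to
1e-8 and satisfying local accuracy. Ranking is the mean absolute Shapley
value, normalized to ratios summing to 1; rows are subsampled (seeded,
default 200) to bound the quadratic path cost. Non-tree models are rejected.

## Numerical and determinism choices

- All generator randomness flows through one `numpy.random.Generator` seeded
  from the config: identical (config, seed) gives byte-identical tables.
- Pair output order: support descending, then lexicographic; node ranking
  ties break lexicographically; relationship columns are in fixed
  lexicographic pair order — the pipeline is order-deterministic end to end.
- Truncated-normal matching solves the cv equation to 1e-12 with brackets
  α ∈ [−60, 60], where the cv is monotone.
- The suspected-infection boundary at exactly 24 h is inclusive ("within
  24 hours" read as ≤).

## Problem sizes

The shipped tests and the acceptance script run the generator at the
published group sizes for distribution checks (455/928 draws), a 120–300
patient cohort for end-to-end runs, and oracle suites at ≤ 12 drugs,
≤ 50 transactions and depth ≤ 3 trees — sizes chosen so the full pipeline
(including 10-seed nested-feature-set comparisons) completes in minutes on
one CPU while leaving every stage exercised at full fidelity.

## Known limitations

- The (I, H, T) algebra is a reconstruction; conclusions tied to the exact
  published formulas should not be drawn from it.
- Real-data performance is out of reach by design: the source cohort is not
  deposited, and the generator's group contrasts are stronger and cleaner
  than hospital data.
- SOFA simplifications listed above; no qSOFA/SIRS/septic-shock
  sub-classification.
- No genomic, radiation or surgical-history features; no NLP over notes.
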