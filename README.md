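# oncosep

Sepsis-risk analysis for cancer cohorts from longitudinal electronic health
records.

Patients with cancer are at elevated risk of sepsis — immunosuppression from
the disease and from chemotherapy blunts the response to infection — yet most
sepsis-prediction work targets ICU trauma populations. `oncosep` implements a
complete, testable analysis pipeline for stratifying sepsis risk among
cancer patients presenting to the emergency room, using only information
available **2–7 days before** the ER visit:

1. **Synthetic cohort generation** — a longitudinal EHR simulator
   (demographics, ER visits, lab panels, same-day prescription baskets,
   bacterial cultures, raw organ-function measurements) with the group
   structure the analysis assumes, so every downstream stage runs without any
   protected data.
2. **Sepsis-3 labeling** — SOFA scores (six organ systems, each 0–4) are
   recomputed at every new measurement; a visit is labeled *sepsis* when the
   SOFA total rises by ≥ 2 points inside a suspected-infection window (a
   bacterial culture with an intravenous antibiotic within ±24 h). An
   unmeasured baseline counts as 0.
3. **Preprocessing** — observation-window filtering, 3-character diagnosis
   codes, a strict >60% lab-coverage filter, robust (median/MAD) outlier
   removal, and mean imputation stratified by cancer type, sex and 5-year age
   bin.
4. **Co-prescription mining** — FP-growth over same-day drug baskets; pairs
   with support `S(Di→Dj) = N(Di,Dj)/N(s) ≥ 0.05` become edges of a
   per-group co-prescription graph ranked by degree and average shortest
   path.
5. **Drug-pair vectorization** — each selected pair's window frequencies
   (x, y) map to three features: interaction `I = x·y`, harmonic intensity
   `H = 2xy/(x+y)`, and angle `T = arctan2(y, x)`; k drugs yield
   `3·C(k,2)` columns (31 drugs → 1395 columns).
6. **Lab screening** — per-lab Welch t-tests between groups with
   significance tiers; labs at p < .001 become model features.
7. **Prediction & attribution** — logistic regression, a 20-tree random
   forest, a feedforward net, a small residual CNN (features zero-padded to a
   42×42 image) and an LSTM, evaluated by stratified 5-fold cross-validation
   on three nested feature sets (`ehr_only` ⊂ `ehr_drug` ⊂ `ehr_drug_lab`)
   with accuracy, AUROC, AUPRC, precision, recall and F1; feature
   contributions ranked by an exact path-dependent Tree-Shapley
   implementation.

Everything is plain scientific Python (numpy/scipy/pandas/scikit-learn/
networkx); FP-growth, Tree SHAP, and the CNN/LSTM (on a minimal numpy
autograd) are implemented in-package and verified against independent
oracles in the test suite.

## Worked example

```bash
oncosep run --seed 11 --n-control 200 --n-sepsis 100 --out summary.json
```

generates a 300-patient cohort, labels it by the Sepsis-3 rule (label
agreement with generator ground truth: **1.0**), mines per-group
co-prescription pairs (15 drugs selected at support ≥ 0.05, including the
narcotic-analgesic pair that passes only in the sepsis group), screens the
lab panel (cholesterol, APTT, PT%, PT-INR and A/G ratio at p < .001 at this
cohort size), and cross-validates a 20-tree random forest:

```
random_forest/ehr_only      auroc 0.617  f1 0.408
random_forest/ehr_drug      auroc 0.946  f1 0.849
random_forest/ehr_drug_lab  auroc 0.960  f1 0.858
```

The monotone gain across the nested feature sets is the pipeline's central
claim: co-prescription structure and screened lab values carry sepsis signal
beyond demographics and diagnosis codes. (Absolute values reflect the
synthetic generator's strong group contrasts, not real-data performance.)

The same stages are available individually (`oncosep generate / label /
features / mine / labstats / train`) and as library calls
(`oncosep.run_analysis`, `oncosep.generate_cohort`, `oncosep.label_cohort`,
...).

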