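# lumcna

Copy-number-alteration (CNA) burden scoring and survival analysis for luminal
breast cancer cohorts.

Luminal (PAM50 luminal A / luminal B) tumours make up roughly 70% of breast
cancers, and the two subtypes are increasingly seen as a continuum ordered by
genomic instability rather than a strict dichotomy.  `lumcna` implements a
simple, statistically robust pipeline for asking whether a patient's CNA
burden carries prognostic information beyond the standard clinical variables:

1. **CNA Score** — for each patient, the sum of the absolute discrete
   copy-number calls over all genes,
   `score_i = Σ_g |c_{gi}|`, with calls `c ∈ {−2, −1, 0, +1, +2}` (homozygous
   deletion … high-level amplification, cBioPortal `data_CNA` dialect).
2. **Ranked quartiles** Q1–Q4 of the score distribution (Q4 = most unstable
   quarter), with thresholds at the empirical 25/50/75th percentiles.
3. **Univariate survival analysis** — Kaplan–Meier curves, median survival
   (with a `not reached` sentinel), and the k-group log-rank test, for both
   overall survival (OS) and disease-specific survival (DSS), in months.
4. **Confounder screening** — log-rank / univariate Cox screening of clinical
   variables against survival; χ², Fisher-exact (Monte-Carlo for r×c tables)
   and Kruskal–Wallis tests of each variable against the quartile grouping.
5. **Multivariable Cox proportional-hazards model** with a
   quartile-by-subtype interaction,
   `h(t|x) = h₀(t)·exp(β'x)`, fitted by Newton–Raphson on the Efron partial
   likelihood, with likelihood-ratio / Wald / score tests, Breslow baseline
   hazard, covariate-adjusted survival curves, reference-level
   reparametrization, and Grambsch–Therneau proportional-hazards diagnostics
   from scaled Schoenfeld residuals.
6. **Recursive-partitioning survival trees** with maximally selected
   log-rank splits (Bonferroni-adjusted) over clinical covariates and the raw
   CNA Score or the ordinal quartile, to locate optimised cut-points.
7. **Cross-stratification** of CNA quartiles against published
   expression-based quantile labels (q1–q4), with high-risk block overlap
   summaries.

All survival machinery is implemented from scratch in `lumcna.survkit`
(lifelines / scikit-survival are used only as independent oracles in the test
suite).  A synthetic METABRIC-like cohort generator (`lumcna.synth`) makes
every stage testable without downloading patient data: it simulates a
gene-level CNA matrix whose burden differs by subtype, clinical covariates,
and survival times from a proportional-hazards model whose default true
coefficients are the published final-model estimates, with administrative
censoring calibrated to ~130.5 months mean follow-up (maximum 337).

## Worked example

Simulate a 400-patient cohort and run the full pipeline:

```sh
cat > demo.yaml <<EOF
n_patients: 400
n_genes: 2000
EOF
lumcna simulate --config demo.yaml --outdir demo --seed 7
lumcna run --cna demo/data_CNA.txt --clinical demo/clinical.tsv \
           --quantiles demo/quantile_labels.tsv --outdir demo_out --seed 7
```

`demo_out/report.md` then starts:

```
Cohort: 400 patients; quartile thresholds 285 / 447 / 673.

## OS
- median OS in Q1: 231.81 months
- median OS in Q2: 244.71 months
- median OS in Q3: 123.98 months
- median OS in Q4: 110.04 months
- log-rank across quartiles: chi2=17.93, df=3, p=<0.001
```

Patients in the upper CNA quartiles die earlier, and the four OS curves
differ (log-rank p < 0.001).  The rendered Cox table
(`demo_out/cox_dss.txt`) reports Beta / SE / HR / 95% CI / P-value per term
with the usual significance codes; in this run the luminal-B main effect is
HR ≈ 2.8 and the quartile main effects increase Q2 → Q4, with negative
quartile-by-subtype interactions — the burden effect is concentrated in the
luminal-A stratum, which is exactly the pattern the generator encodes.
Other artifacts: per-quartile KM tables with risk counts, screening reports,
Cox fits as JSON, PH-diagnostic tables, the survival tree (JSON + text) and
the quartile × expression-quantile crosstab.

The same analyses are available as library functions:

```python
from lumcna import (read_cna_matrix, read_clinical, score_and_quartile,
                    fit_cox_model, logrank_test)

cna = read_cna_matrix("demo/data_CNA.txt")
clinical = read_clinical("demo/clinical.tsv")
score = score_and_quartile(cna)           # scores, thresholds, Q1..Q4
fit = fit_cox_model(clinical, score, outcome="DSS")
print(fit.summary())
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the parameter-recovery benchmark from scratch: it generates 50
synthetic cohorts of n = 1175 from the default configuration (true
coefficients = the published final-model estimates), recomputes scores and
quartiles through the real scoring path, refits the 13-term Efron-ties Cox
model to each cohort's DSS outcome with this package's implementation, and
writes the mean estimated luminal-B main-effect log-hazard coefficient to the
JSON file.  Runtime is a few minutes on one CPU.

Published values that depend on the real METABRIC data (quartile thresholds,
Q4 medians, the tree cut-point) are encoded as flagged integration checks in
`lumcna.reference`; run the pipeline on the cBioPortal `brca_metabric`
download and compare with `lumcna.reference.run_integration_checks`.

See `docs/methods.md` for the statistical methods, the generator's design and
its limitations.
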