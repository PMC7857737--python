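# Methods

## CNA Score and quartile segmentation

The per-patient burden metric is the sum of absolute discrete copy-number
calls over all genes in the input matrix.  Missing calls contribute 0 and are
counted and logged; this preserves cohort size under sporadic missingness at
the cost of slightly deflating the affected patients' scores.  Duplicate gene
symbols are kept as distinct rows keyed by (symbol, gene id) — deduplicating
would silently change scores.  The metric deliberately ignores segment
length, direction of change and genomic location; it is a first-order
genomic-instability summary, not a fine-grained landscape model.

Quartile thresholds are lower empirical order statistics (type-1 quantiles):
`t_k = x_(⌈k·n/4⌉)` on the sorted scores, so each threshold is an attained
integer score.  A patient is in Q1 if `score ≤ t1`, Q2 if `t1 < score ≤ t2`,
and so on; ties at a threshold therefore fall into the lower quartile.  With
all scores distinct and n divisible by 4 each quartile holds exactly n/4
patients; a fully degenerate distribution collapses into Q1 with a warning.
Q1 is the reference level in every downstream model.

## Survival machinery (survkit)

*Kaplan–Meier* is the standard product-limit estimator; the median is the
smallest event time with S(t) ≤ 0.5, reported as `not reached` (None) when
the curve never crosses 0.5 within the observed range.

*Log-rank* is the k-group O−E statistic with the hypergeometric
(multiple-draw) variance, df = k−1.  Note the classical identity "two-group
log-rank = Cox score test under Breslow ties" is exact only in the absence of
tied event times, because the hypergeometric variance carries a
(n_j−d_j)/(n_j−1) tie factor the partial-likelihood information does not;
the test suite asserts the identity to 1e-8 on continuous-time cohorts.

*Cox regression* maximises the partial likelihood by Newton–Raphson with the
Efron tie correction (Breslow available), tolerance 1e-9 on the relative
log-likelihood change, at most 50 iterations, step-halving on non-increase.
Covariate columns are centred internally for numerical stability — the
partial likelihood is exactly invariant to covariate shifts, so estimates
and covariance are unaffected and the baseline hazard is re-referenced to a
zero design row afterwards.  The covariance is the inverse observed
information; confidence intervals are Wald intervals on the log scale with
z = 1.959964; likelihood-ratio, Wald and score chi-square statistics are all
reported.  A coefficient passing |β| > 20 triggers a monotone-likelihood
(separation) warning.  The baseline cumulative hazard is the Breslow
estimator at the fitted coefficients; adjusted curves for a covariate
profile x are S(t|x) = exp(−H₀(t))^{exp(β'x)}, with non-stratum covariates
fixed at medians (quantitative) or modes (categorical).

*Design matrices* use treatment coding with declared reference levels
(luminal A, grade 1, HER2-negative, CNA Q1); interactions are elementwise
products of the marginal dummy blocks.  The final model has 13 columns:
subtype, grade (2), three quantitative covariates, HER2, quartile (3) and
quartile-by-subtype (3).  Formulas are a deliberately tiny language —
variable names, `+`, and `:` — because nothing richer is needed.

*PH diagnostics* regress scaled Schoenfeld residuals on the time transform
g(t) = 1 − KM(t) (left-continuous, all-cohort KM) and report per-term and
global chi-square tests using the Grambsch–Therneau approximation with the
average residual variance I/d.  This matches lifelines'
`proportional_hazard_test` (km transform) to ~1%; modern R `cox.zph` uses a
refined variance and can differ slightly in the third digit.

*Reparametrization* refits with a new reference level; within-stratum
contrasts of the original fit (e.g. βQ4 + βQ4:lumB) equal the corresponding
main effects of the refit, which the tests assert together with the
invariance of the fitted log-likelihood.

## Association battery

Categorical×categorical: Pearson χ² without continuity correction when all
expected counts are ≥ 5, else Fisher's exact test — exact two-sided
hypergeometric for 2×2, margin-preserving Monte Carlo (Patefield sampling,
10 000 tables by default, add-one correction (1+extreme)/(reps+1)) for r×c.
Continuous×quartile: Kruskal–Wallis with midrank tie correction; a constant
variable reports p = 1 with a warning.  Survival screening uses the log-rank
test for categorical variables and the univariate Cox Wald test for
continuous ones, selecting at α = 0.05 with no multiple-testing correction
(both overridable); this mirrors a deliberately permissive first-pass screen,
not a confirmatory analysis.

## Survival trees

Each node evaluates every predictor: continuous variables over midpoints
between consecutive distinct values, ordinal variables (the quartile) over
order-respecting cuts only (Q1|Q234, Q12|Q34, Q123|Q4), nominal variables
over binary level partitions (≤ 10 levels).  The split statistic is the
two-group log-rank chi-square, computed for all candidates of a variable in
one vectorised scan; the winning candidate's p-value is Bonferroni-adjusted
by the number of candidates actually evaluated.  Splitting requires
adjusted p < α (default 0.05) and `min_node` = 20 subjects on both sides.
This is a deterministic, fully specifiable stand-in for conditional-inference
survival trees; Bonferroni is conservative relative to the permutation null,
so cut-points found on real data are comparable but not guaranteed identical
to the original framework's (the published METABRIC cut of 5882 is therefore
an approximate integration check, see `lumcna.reference`).

## Synthetic cohort generator

The generator emulates a METABRIC-like luminal cohort at whatever scale is
requested; the defaults are the stated world of the benchmark suite:

| parameter | default | rationale |
| --- | --- | --- |
| n_patients | 1175 | luminal cohort size |
| n_genes | 22 247 | gene count of the cBioPortal `data_CNA` file |
| P(lumB) | 0.42 | approximate luminal-B fraction among luminal cases |
| alteration rate | Beta(2.0, 9.1) lumA; Beta(2.5, 5.8) lumB | per-patient gene-alteration probability; means 0.18 / 0.30 so lumB is stochastically more unstable |
| call weights (−2,−1,+1,+2) | 0.05/0.45/0.40/0.10 | deletions and single-copy changes dominate |
| covariates | age N(61,10²); size lognormal(3.1,0.5²) mm; nodes NB(0.8,0.35); grade and HER2 subtype-dependent | realistic marginals; drawn independently |
| true coefficients | the published 13-term final-model estimates | parameter-recovery target |
| baseline hazard | exponential, 3.9e-3 /month after centring the linear predictor | calibrated (with censoring) to ≈35% DSS events |
| censoring | uniform entry over 0.82·337 months, horizon 337 | administrative; calibrated to mean follow-up ≈130.5 months |
| P(disease death \| death) | 0.70 | thins OS events to DSS events; thinning preserves proportional hazards with the same coefficients |

The Beta-distributed per-patient alteration rate is the key modelling choice:
real CNA profiles are segment-correlated (whole arms gained or lost
together), which makes real burden scores widely dispersed.  Independent
per-gene calls with a fixed rate would concentrate scores so tightly that
quartile membership would become a deterministic function of subtype and the
interaction design would be near-singular.  The Beta spread stands in for
that correlation at the patient level; it reproduces wide, overlapping
subtype score distributions (cohort thresholds land near 3000/5300/8200 at
the default scale) without modelling genomic position.  What a green test
does *not* establish: anything about gene–gene or covariate–covariate
correlation structure, segment lengths, or the real joint distribution of
clinical covariates — none of which the burden metric itself uses.

Quartile membership entering the linear predictor is computed from the
generated scores through the real scoring path (not pre-assigned), so
end-to-end tests exercise the same code path as real data.  Expression
quantile labels are generated from a latent standardized score plus logistic
noise (scale 1.5), sliced into cohort quarters — label probability increases
with burden, giving the quartile × quantile gradient the crosstab analysis
expects.  One global seed drives named substreams (subtype, CNA, covariates,
times, censoring, labels) so components can be varied independently.

The baseline rate and accrual fraction were calibrated once by simulation to
the two stated follow-up targets and frozen; they were not revisited after
observing test outcomes.

## Benchmark design choices

*Change-point recovery*: the tree benchmark draws scores on a 0..100 grid in
steps of 10 (≈36 subjects per level at n=400) with a log-hazard jump of 1.2
above 50.  On a fine integer grid the "cut recovered between the flanking
distinct scores" criterion is not attainable at 90% even with extreme
effects (the maximally selected cut estimate scatters over neighbouring
values); the coarse grid makes exact-partition recovery a well-posed ≥90%
benchmark (~99% observed).

*Quartile-ordering check*: the true Q3 and Q4 log-hazards differ by only
0.072, which single cohorts of n=5000 cannot resolve, so the lumA KM
ordering invariant is asserted on curves averaged over 10 replicate cohorts.

*Type-I error bands*: simulation calibration tests use 3-binomial-SE bands
around the nominal 5% over 200 replicates.

## Numerical and degenerate-input conventions

Times are months throughout; OS events are deaths from any cause, DSS events
deaths from disease with other-cause deaths censored at the death time.
P-values are stored at full precision; the "<0.001" truncation and the
significance codes `0(***) 0.001(**) 0.01(*) 0.05(.) 0.1()` exist only in
report rendering.  Degenerate inputs: empty survival input, single log-rank
group, event-free Cox data, collinear designs, zero-margin contingency
tables, empty crosstab intersections and empty predictor lists raise
ValueError with actionable messages; constant Kruskal–Wallis input and
degenerate score distributions warn and return the conventional neutral
value.

## Known limitations

No time-varying covariates, stratified/penalized Cox, frailty or competing
risks; no exact network algorithm for r×c Fisher; no tree pruning or random
survival forests; the generator does not model genomic position, segment
length, gene–gene correlation or covariate correlations.  Published
cohort-dependent headline values require the real cBioPortal download and
live in `lumcna.reference` as flagged integration checks rather than tests.
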