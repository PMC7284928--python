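# Methods

## Model and procedure

The pipeline treats each case/control expression study as an independent
estimate of a gene's log2 fold-change (LFC) and asks three questions per
gene: what is the pooled LFC across studies, is the between-study variation
compatible with sampling noise, and does the pooled change agree — in
significance and in sign — with what the literature network predicts for a
gene connecting the driver (PPARG) to the disease (MI).

### Effect sizes

Per study, LFC = mean(case) − mean(control) on the log2 scale. The sampling
variance is Welch-style, s²₁/n₁ + s²₂/n₂ with unbiased group variances:
group variances are not pooled because the cohorts come from different array
platforms with different noise levels. Missing values are excluded pairwise;
genes with fewer than 2 usable samples in a group are skipped for that
study; rows with more than 20 % missing values are dropped at ingest. A gene
with zero spread in both groups receives a variance floor of 1e−8 so it
cannot acquire unbounded meta-analysis weight (the estimate is still
reported; only its weight is capped).

### Pooling and model selection

Fixed effects is classical inverse-variance pooling. Heterogeneity is
Cochran's Q with df = k − 1, I² = max(0, 100·(Q − df)/Q), and an upper-tail
χ² p-value. Random effects is DerSimonian–Laird. The default selection rule
is *fixed iff Q ≤ df*: heterogeneity no larger than its null expectation is
treated as absent. Note that this is stricter than the common "no
significant heterogeneity" convention — under true homogeneity, the realized
Q exceeds df roughly half the time, so the random model is selected for
about half of genuinely homogeneous genes (harmlessly: with Q near df the DL
τ² is small and the two fits nearly coincide). The significance-based rule
(fixed iff p_Q > threshold) is exposed as `het_p_threshold` for users who
prefer the conventional behaviour.

Pooled p-values use the normal approximation z = pooled/se rather than a
t reference; with the small study counts here (k = 3–8) this is mildly
anticonservative per study, but the calibration check below shows the
overall type-I error stays near nominal because about half the genes fall to
the wider random-effects standard error. p-values are floored at the
smallest positive float so downstream log-transforms are safe. Pooling
requires k ≥ 2 (default `min_k = 2`); no multiple-testing correction is
applied at the network-filter step (the filter operates at raw p < 0.05),
though a BH helper is provided.

### Network candidate mining and classification

Relation tables are directed edges (source, target, polarity). Candidates:

- promoted inhibitors: driver →+ g and g ⊣ disease;
- contra-directional: driver →+ g and disease ⊣ g (expected down), or
  driver ⊣ g and disease →+ g (expected up).

Gene symbols are trimmed and upper-cased before comparison. A gene matching
both the promoted and a contra pattern is assigned to promoted inhibitors
(the two published sets partition); a gene matching both contra patterns is
assigned contra-down with a warning (ambiguous literature polarity). All
relation types participate by default; `restrict_types` narrows the logic to
e.g. expression-regulation edges only, since the admitted types are not
fixed by the source material. Classification keeps a candidate iff pooled
p < α and the LFC sign matches the expectation; candidates without a pooled
result are dropped with a warning rather than erroring, because array
platforms differ in gene coverage.

### Covariate influence (MLR)

Per gene, the k study LFCs are regressed on an intercept, total sample size
(n_case + n_control), study age (years, current year − study year + 1) and
country (dummies against the alphabetically first level). Each factor gets a
partial F-test (type-II: full model vs. model without that factor's
columns). With k as small as 3–8 the design easily exhausts its degrees of
freedom; when residual df < 1 the model drops factors in the order
country → study_age until estimable, and dropped or collinear factors report
p = 1 with a not-estimable flag. A saturated fit (zero residual) reports
p = 1 for factors whose removal changes nothing and the smallest positive
float for factors that carry the fit. Constant responses short-circuit to
p = 1, R² = 0.

### Enrichment

One-sided over-representation only: p = P(X ≥ overlap) under the
hypergeometric law with population = |background|, successes = set size,
draws = |query ∩ background|. BH q-values are computed across the whole
collection before filtering (default thresholds p < 0.005 and q < 0.005, both
configurable and interpreted as two independent cuts). Jaccard similarity is
overlap / (query + set − overlap). The background defaults to the union of
collection members because the enrichment universe of the original analysis
is unknown; p-values therefore depend on that choice, while the Jaccard
values do not — which is why the Jaccard column, not the p column, is the
reproduction target.

## Synthetic data: what it emulates, and what not

`megapath.synthetic` generates the full desk-scale input bundle:

- **Studies**: the eight published cohort designs (control/case sizes
  4/34, 4/34, 48/49, 21/31, 7/10, 7/17, 14/84, 50/49; countries; study
  ages). One accession appears twice with different case counts and is kept
  as two independent sub-studies. Gene baselines are Uniform(4, 12) on the
  log2 scale (a typical microarray range); within-group noise is Gaussian
  with σ = 1.0; study-level true effects are Normal(planted LFC + optional
  covariate slopes, τ²). Defaults plant the nine network genes at their
  published pooled LFCs with τ² = 0, plus one significant wrong-direction
  decoy (+0.5) and several null decoys. Default roster 160 genes — the
  scale of the published candidate mining (30 + 125 candidates).
- **Relations**: the nine-gene driver–disease network (3 promoted
  inhibitors, 3 contra-down, 2 contra-up) plus decoys that fail
  significance, direction, or lack a disease edge.
- **Gene sets**: eight GO-shaped sets whose sizes (370, 730, 761, 803, 422,
  441, 451, 533) and query overlaps (7, 7, 7, 6, 5, 5, 5, 5) mirror the
  published enrichment layout, padded from a shared 5000-gene decoy pool,
  plus query-disjoint decoy sets.

σ = 1.0 deliberately keeps recovery of the weaker planted effects
(|LFC| 0.16–0.23) marginal at the published sample sizes — per-gene power
ranges from ~0.3 to ~1.0 — so a default-noise end-to-end run typically
recovers a subset of the eight network genes, mirroring the marginal
published p-values (0.03–0.05) rather than guaranteeing a showcase result.
Tests that need deterministic full recovery lower the noise explicitly.

Not emulated: platform-specific probe chemistry, probe-level structure
(the simulator emits gene-level rows; probe collapsing is exercised on
separate fixtures), batch effects beyond study-level covariate slopes,
correlated genes, and non-Gaussian heavy tails of real microarray noise.
Passing tests therefore demonstrate the statistical machinery and plumbing,
not robustness to real-data artefacts.

## Numerical choices

- Linear-scale detection at ingest: max > 50 triggers log2(x + 1); both the
  threshold and pseudo-count are arguments. Negative values in a matrix
  judged linear are an error.
- Probe aggregation default `max_mean` (keep the probe with the highest mean
  signal); `mean` and `median` available.
- Q ≤ df ties select the fixed model (boundary counted as homogeneous, so
  I² = 0 exactly at Q = df).
- DL denominator c = Σw − Σw²/Σw; τ² = 0 if c ≤ 0 (degenerate single-weight
  case).
- Output TSVs use 6-significant-digit formatting; reruns with identical
  config and inputs are byte-identical.
- All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`.

## Verification

The pooling path is checked against independent routes: a numerical
weighted-least-squares minimiser for the fixed-effects estimate, step-by-step
recomputation of Q and DL τ² from their definitions, and R's `metafor`
(`rma`, methods FE and DL) on a reference instance. The MLR partial-F path is
checked against `statsmodels` type-II ANOVA. Hypergeometric p-values are
checked against exhaustive combinatorial enumeration for backgrounds up to
30 genes. Calibration: 10,000 null genes simulated under the eight published
designs give a type-I error at p < 0.05 inside [0.04, 0.06]. Recovery:
planting LFC = −0.52 over the first five designs recovers the effect within
3 pooled SE in ≥95 % of replicates; because the realized Q is random, the
fixed model is selected in roughly half the replicates under the default
rule (and in the overwhelming majority under `het_p_threshold = 0.05`),
which the tests assert as such rather than as a certainty.

## Limitations

- Real-data ingestion from GEO is supported by the readers but untested
  here (requires downloads); published per-gene pooled values from the real
  cohorts are not reproduced by the synthetic bundle.
- The z-based pooled p-value ignores the uncertainty of the per-study
  variance estimates; with groups as small as n = 4 the realized Q is
  slightly over-dispersed relative to χ², which shifts model selection
  toward random effects more often than the nominal rule implies.
- Plain OLS meta-regression (no within-study variance weighting) for the
  covariate influence analysis, matching the original design; a
  weighted/mixed-effects meta-regression would be the modern choice.
- The enrichment background is a modelling choice; results tables should
  always be read together with the background size recorded in the manifest.
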