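# Methods

This note records the statistical conventions, defaults, and design
choices behind `icbbench`, and what the synthetic-cohort tests do and do
not demonstrate about real data.

## Expression conventions

All scoring operates on genes × samples matrices of log2(TPM+1) values
with HGNC gene symbols.  `tpm_log_transform` applies the packaged unit
convention (0 TPM ↦ 0).  Duplicate gene symbols are collapsed by the
per-sample maximum — a common multi-transcript convention; the collapse
count is logged.  Gene z-scoring uses the population SD (ddof = 0) for
determinism; zero-variance rows become all-zero and are flagged.  TSV
round trips are lossless: writing uses 17 significant digits and reading
uses exact-rounding float parsing.

## Score families

* **Means / weighted sums.**  Arithmetic on the log scale.  CYT's
  published geometric mean of TPM equals the arithmetic mean in log
  space, so the mean family covers it.
* **IMPRES.**  Count of pairs (g₁, g₂) with x_{g₁} strictly greater than
  x_{g₂}; ties contribute 0, making the score a deterministic integer in
  [0, n_pairs].  Rank-based, hence invariant to any strictly increasing
  per-sample transform.
* **ssGSEA** (APM, C-ECM-up, TIS subsets).  Per sample, genes ranked by
  decreasing expression (average ranks at ties; the top gene has rank
  value N).  Walking top-down, an in-set gene advances the walk by
  rank^α normalized over the set (α = 0.25 by default) and a miss
  retreats it by 1/(N − |set|).  The ES is the sum of the walk (integral
  form).  No across-sample ES normalization is applied by default; both
  α and the optional normalization are exposed in `EnrichmentParams`.
* **TIS.**  ssGSEA ES per T-cell subset, z-scored across samples
  (population SD), averaged over the nine subsets; the column therefore
  has sample mean 0.  If any subset is incompletely measured the whole
  score is missing.
* **GSVA-mean** (IPRES).  Per gene, a Gaussian-kernel cumulative density
  across samples with Silverman's-rule bandwidth (0.9·min(sd, IQR/1.34)·
  n^{−1/5}); per sample, sets are scored by a linear-rank-weighted walk
  whose ES is the deviation of largest magnitude (sign preserved); the
  final score is the mean over the collection's sets.  This is a
  desk-scale implementation of the GSVA family; the kernel bandwidth rule
  is a declared choice (the R implementation uses sd/4) and the
  construction is documented as an approximation.  Requires ≥ 2 samples.
* **PC1** (Pan-F-TBRS).  First principal component of the z-scored
  member-gene submatrix with samples as observations.  PCA sign is
  arbitrary, so the score is oriented to correlate positively with the
  members' mean expression — a TGF-β response score must increase with
  its response genes.
* **Up-minus-down** (IRP).  Mean gene-centered expression over the up
  program minus the down program.
* **IPS.**  Gene z-scores across samples, averaged within weighted
  components, component scores averaged per category (MHC, EC, SC, CP),
  category scores averaged, and the aggregate mapped affinely to
  [0, 10]: 0 at aggregates ≤ 0, 10 at ≥ 3, linear between.  The map
  constants and the component tables ship as configuration.
* **MCP-counter.**  Per-population arithmetic mean of marker-gene log
  expression.
* **External** (CIBERSORT.CD8, TIDE).  Consumed as precomputed per-sample
  columns; no deconvolution or dysfunction/exclusion model is
  reimplemented here.

All families are deterministic and permutation-equivariant in samples.

## Coverage rule

A biomarker is evaluable on a matrix only if the fraction of its genes
present reaches the threshold (default 1.0 — every gene required, the
appropriate rule when panel platforms such as NanoString measure only
some genes).  Non-evaluable biomarkers get missing scores, never partial
ones.  The threshold is configurable for RNA-seq users tolerating small
gaps.

## Signature data files

Gene lists, weights, pairs, and scheme tables are transcribed from each
biomarker's original publication into `data/signatures.yaml` and are
deliberately configuration rather than code, so corrected transcriptions
can be substituted without touching the package.  For programs whose
published supplements run to hundreds of genes (IRP, IPRES, C-ECM-up) the
packaged lists are representative core-member transcriptions.  The IS
biomarker's original form is a Bayesian posterior over an immune
signature; the packaged reconstruction scores the mean of the signature's
member genes, a monotone surrogate for that posterior, and is flagged as
such in the data file.

## Response labeling

Strict inequalities gate stable disease: SD is a responder under `OS`
only with overall survival > 1 year and under `DCB` only with
progression-free survival > 6 months; boundary equality is a
non-responder.  Calendar conversions default to 365.25 days/year and
182.625 days/6 months and are per-dataset configuration, since cohorts
report time in different units.  Samples without a RECIST category are
unevaluable for labeling but still scored; SD samples missing the gating
time under `OS`/`DCB` are marked unevaluable rather than dropped
silently.  ORR = (CR+PR)/evaluable patients.

## Statistics

* **Wilcoxon rank-sum.**  Exact null distribution when the pooled sample
  is ≤ 20 and tie-free; otherwise a normal approximation with tie
  correction and a signed continuity correction (applied toward zero), so
  identical groups report p = 1 exactly.  Reported p-values are floored
  at 10⁻⁵; the raw value is retained alongside.
* **Logistic regression.**  The score is standardized to unit population
  SD before the univariate fit, so odds ratios read per score-SD; CI and
  p are Wald.  Perfect separation returns a flagged infinite-OR sentinel
  instead of raising.
* **ROC/AUC.**  Mann–Whitney form: concordant pairs plus half the ties.
  Scores are oriented by the biomarker's documented response direction
  first (negative markers are negated), so every AUC reads "higher =
  more predictive in its direction"; the raw unoriented AUC is reported
  too.
* **Prediction Score.**  Sample-size-weighted mean of per-dataset AUCs;
  a biomarker's training datasets (a per-signature config field) are
  dropped before aggregation.  Stratified scores recombine exactly to
  the overall score under the same weights.
* **Median split.**  Strictly above the median → high, strictly below →
  low; median-tied samples join the smaller strict group, with the size
  tie broken toward low.  The split is exhaustive and its imbalance is
  bounded by the number of median-tied samples.  All-equal scores admit
  no split and are flagged.
* **Fisher/ORR.**  Two-sided by the point-probability convention, on the
  2×2 of median-split group × objective response; computed only in
  datasets with more than 20 patients.  Degenerate margins give p = 1
  with a warning.
* **Survival.**  Patients contributing more than one sample are excluded
  entirely.  Product-limit curves and the Mantel–Haenszel log-rank
  statistic (χ²₁) come from lifelines; events precede censorings at tied
  times.  Median survival is the earliest time with S(t) ≤ 0.5
  (undefined when never reached).  Landmark survival (default 24 weeks)
  carries a Greenwood 95% CI computed on the log-survival scale and
  clipped to [0, 1].  Significance is flagged at p < 0.05.
* **Correlation structure.**  Pairwise Spearman ρ over shared
  non-missing samples; constant rows are excluded with a warning;
  average-linkage clustering on 1 − ρ yields the dendrogram leaf order.

## Synthetic cohorts

The generator draws a latent responder class per patient and builds
everything from it: Gaussian log-expression (truncated at 0) around
gene-specific baselines in [3, 8], planted signatures shifting member
genes by d noise-SD units in responders (sign flipped for
negative-direction biomarkers), RECIST categories from per-class
probability vectors, and exponential OS/PFS with uniform censoring whose
horizon is solved numerically to hit the configured censoring fraction.
Defaults mirror the make-up of the public ICB benchmark cohorts: a
responder fraction of 0.5 under the `PD` definition and CR+PR mass of
0.56 within latent responders, giving an overall ORR near 28%; responder
OS hazard half the non-responder hazard (median 60 vs 30 weeks);
20% censoring.  Dataset sizes default to tens of samples per dataset,
the scale of the real cohorts; heavier recovery checks use a single
4000-sample dataset so binomial error stays below the ±0.02 recovery
band.  A single seed drives one SeedSequence with per-dataset
substreams, so output is bitwise reproducible.

For a k-gene mean signature with planted shift d, the score separates the
classes by d·√k SDs, so AUC = Φ(d·√k/√2).  The tests verify the full
simulate → score → evaluate pipeline recovers this analytic target.

What the simulator does **not** model: co-expression structure, batch and
platform effects, count-level noise, tumor purity, or any dependence of
survival on expression beyond the latent class.  Passing recovery tests
therefore demonstrate the correctness of the machinery, not the clinical
performance of any biomarker on real cohorts.

## Degenerate inputs and tie-breaks

Empty sample intersections, single-sample z-scores/GSVA, all-constant
PC1 submatrices, gene sets spanning the whole universe, single-class
ROC/logistic inputs, and all-equal median splits raise informative
errors; degenerate survival splits and no-event log-rank comparisons are
flagged (p = 1) rather than raised, since they occur naturally inside
large benchmark loops.  Stable sorts fix walk order among tied ranks.

## Known limitations

* The packaged signature transcriptions are best-effort reproductions of
  cited supplements and should be reviewed (and can be replaced) before
  scientific use.
* GSVA and ssGSEA defaults are declared approximations of the cited tool
  family, not byte-compatible reimplementations.
* No multiple-testing correction is applied across biomarkers, matching
  the benchmark's reporting of unadjusted p-values.
* Cox models, competing risks, AUC confidence intervals, CIBERSORT
  deconvolution, and the TIDE model are out of scope.
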