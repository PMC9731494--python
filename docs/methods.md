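# Methods

This note documents the statistical procedures implemented in
`proteoclust`, the assumptions behind the synthetic-cohort generator,
and the design decisions taken where the analysis recipe left choices
open.

## Intensity standardization

Aptamer panels report relative fluorescence (RFU) contaminated by
per-sample hybridization efficiency, per-plate batch scale and residual
per-sample signal level.  `standardize` removes these with four
median-ratio scalings:

1. *Hybridization normalization* — each sample is divided by the ratio
   of its hybridization-control median to the run-wide median of those
   probes.  This is the only step applied to the control columns.
2. *Plate scaling* — each plate's biological columns are multiplied by
   (grand median of plate medians) / (plate median), where a plate
   median is the median of its samples' per-sample medians.
3. *Median signal normalization* — each sample's biological columns are
   scaled so the per-sample median equals the run-wide median; when
   dilution groups are annotated the step runs within group.
4. *Calibration* — each plate's biological columns are multiplied by the
   median ratio of reference calibrator levels to the plate's calibrator
   medians.  Without an external reference the run-wide calibrator
   medians serve as the reference, making the step a cross-run alignment
   that is a no-op within a single already-hybridization-normalized run.

Steps 2–4 estimate biological-signal scale, so they are computed from
and applied to biological columns only; control probes carry pure
technical scale.  This separation is what makes the procedure
*idempotent*: the four steps are cycled (default) until every fixed
point holds jointly, which the structure above reaches in two or three
sweeps, after which re-running `standardize` is the identity to machine
precision.  An earlier design in which calibration rescaled every
protein per plate was abandoned because per-sample and per-protein
median constraints are mutually inconsistent on finite data — the
alternation oscillates at the percent level and never satisfies the
fixed points.  A `single_pass=True` switch applies the literal 1→4
sweep once.

`standardize` refuses matrices already tagged as normalized,
non-positive intensities and zero control medians.  The per-sample
factor it removed is reported (`NormalizationInfo.sample_factor`, read
off the hybridization controls) and, on generator output, reproduces
the planted hybridization-drift × plate factors with correlation > 0.99
(in practice ≈ 1.0).

## Cluster discovery

Subjects are clustered on the top `fraction` (default 10%, `floor` of
the candidate count) of non-control proteins ranked by across-subject
standard deviation of log2 intensity (ties broken by column order).
Log2 values are already variance-stabilized, so plain SD rather than CV
is used.  Each selected protein is z-scored; subjects are merged by
Ward's method on Euclidean distance and the tree is cut at k = 2.  The
distance/linkage pair is the standard heatmap-clustering default and is
configurable; determinism follows from scipy's tie-breaking by smallest
index.

Cluster numbers from a tree cut are arbitrary, so labels are
canonicalized: the group with more significantly up-regulated proteins
becomes **Cluster 2**; a tie falls back to the higher mean per-subject
median over the clustering panel.  The applied rule is recorded in
`ClusterResult.label_rule`.

On structure-free (healthy) cohorts the forced two-way split is
unstable across seeds by construction; this is a diagnostic, not an
error, and the score-transfer test below is the intended null check.

## Moderated differential expression

Per protein, the two-group contrast Δ = mean₂ − mean₁ of log2 values is
tested with an empirical-Bayes moderated t.  The pooled within-group
variance s²_g (d_g = n₁ + n₂ − 2 df) is shrunk toward a prior variance
s₀² with d₀ prior df:

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)
    t_g = Δ_g / (s̃_g √(1/n₁ + 1/n₂)),   t_g ~ t(d₀ + d_g) under H₀.

The prior is fitted by method of moments on log s²_g using the exact
log-chi-square moments (digamma/trigamma), with the trigamma inverse
solved by Newton iteration; when the observed spread of log variances
does not exceed chi-square sampling variation, d₀ = ∞ and every protein
receives the pooled prior variance.  The implementation agrees with the
reference empirical-Bayes implementation in R/Bioconductor (limma) to
~1e-14 on a frozen fixture, reduces exactly to the ordinary
equal-variance t test at d₀ = 0, and to a z-like statistic at d₀ = ∞.
Constant proteins under d₀ = 0 are flagged and assigned p = 1.

Multiple testing uses Benjamini–Hochberg step-up q-values across all
assayed non-control proteins (not only the clustering panel — the
volcano spans the panel-wide comparison; a `proteins=` argument
restricts it).  Significance is the strict magnitude rule *fold change
2^|Δ| > 1.5 and q < 0.05*; direction is carried separately so the rule
applies symmetrically to both sides.

## Protein score and signature

The protein score of a subject is the median log2 expression over a
designated up-regulated set (by default the Cluster-2 up-set of the
learning stage).  Group comparison uses the two-sided
Wilcoxon–Mann–Whitney rank-sum test: exact when both groups have ≤ 25
subjects and the pooled scores are tie-free, otherwise the normal
approximation with tie correction.  The score is reported with
per-cluster medians.

The short signature (defaults 11 Cluster-2 + 4 Cluster-1 proteins,
configurable) is a pure function of the DE, enrichment and odds-ratio
tables:

* Cluster-2 side: candidates are the top decile (by |log2fc|) of
  significant up-regulated proteins; each candidate is assigned to its
  most-enriched annotated term (smallest q); families are visited in
  enrichment order taking the member with the strongest clinical odds
  ratio (largest |log OR| over the configured outcomes), with a second
  round over families if the quota is not filled — the one-per-family
  quota with overflow by enrichment rank is an interpretation of the
  "representative of highly enriched pathways" idea and is recorded as
  such.
* Cluster-1 side: significant down-side proteins minus an exclusion
  list (proteins that failed external replication), top |log2fc|.

Every decision is appended to `selection_log`, and the output is
invariant to row permutation of the inputs.  When fewer candidates than
requested exist, all are returned with a warning record.

## Enrichment and clinical statistics

Over-representation uses the upper-tail hypergeometric probability
P[X ≥ k] with the full assayed non-control panel as the default
universe, BH adjustment across terms, and a q < 1e-4 reporting filter
(the full table is always returned).  Only over-representation is
tested.  Set-to-set overlap reports k, the integer-rounded percentage of
the reference set, and the same upper-tail p.

Clinical comparison tables use the two-sided equal-variance t test for
continuous variables and Fisher's exact test for categorical ones
(2×2 via scipy; r×2 by full enumeration of fixed-margin tables under
the probability-mass two-sided rule, falling back to chi-square above
200 observations).  The 2×2 odds ratio reported is the sample ratio
ad/bc, flagged infinite on zero off-diagonal cells.

Per-protein outcome models are univariable logistic regressions fitted
by IRLS (deviance tolerance 1e-8, ≤ 100 iterations).  Expression is
standardized per protein, so the odds ratio is *per SD of log2
expression* — the unit matters for magnitudes and is therefore stated
prominently; `standardize=False` gives per-log2-unit ratios, and on a
0/1-encoded predictor the fit reproduces ad/bc exactly.  Wald 95%
intervals and BH q-values are computed within outcome.  Separated fits
are flagged, refitted with a tiny ridge so the coefficient stays at a
finite bound, and reported with p = 1 and an infinite-width interval
rather than dropped.

## Validation and switching

Transfer validation is agnostic: the new cohort is variance-filtered,
clustered and canonicalized *using only its own data*; the learned
up-set enters afterwards, to score the new clusters (rank-sum test) and
to measure the overlap between the new and learned up-sets
(hypergeometric).  The overlap percentage is reported relative to the
new cohort's up-set.

Paired visits are clustered independently per visit.  Each subject's
visit-2 destination is Cluster 1, Cluster 2 or *mixed*: mixed means the
visit-2 protein score lies strictly inside the middle band of the
segment joining the two visit-2 cluster score medians — by default
between the ¼ and ¾ points, i.e. `(m_lo + 0.25 Δ, m_lo + 0.75 Δ)` with
Δ = m_hi − m_lo.  The band fractions are configurable and equal
fractions collapse the band, reducing the analysis to a plain 2×2
transition table.  A within-cluster quantile rule (e.g. "between the
high cluster's 25th and the low cluster's 75th percentile") was
rejected: empirical within-cluster quartiles mark a fixed ~25% flank of
each cluster as mixed no matter how well separated the clusters are,
which misclassifies stable subjects by construction.  Mixed profiles
have no agreed operational definition in this field; results citing the
band rule are labeled with the zone actually used
(`TransitionTable.mixed_zone`).  Concordance counts subjects with the
same non-mixed identity at both visits; the association test is
Fisher's exact on the 2×2 collapse with mixed folded back into the
visit-2 cluster label.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets:

* log2 biological baselines ~ N(10.6, 1.0) per protein — the baseline
  location matches a healthy-serum median log2 score of ≈ 10.6;
* two planted clusters with additive log2 effects (multiplicative in
  RFU) drawn once per protein from U[0.8, 1.5], constant across
  subjects — the lower bound exceeds log2(1.5) so planted effects are
  detectable under the significance rule;
* within-group residual noise sd 0.5 on the log2 scale, matching a
  healthy-cohort score spread of ≈ 0.1–0.2 at a 90-protein median;
* per-sample hybridization drift (lognormal, σ = 0.05) and per-plate
  factors (lognormal, σ = 0.10) over 4 plates (1–2 for the small
  cohorts);
* 3 hybridization-control and 3 calibrator probes that carry the
  technical factors but no biology and no noise (synthetic spike-ins),
  included in the 1305 assay columns;
* binary clinical covariates drawn per subject conditional on cluster,
  with default prevalences (Cluster 1, Cluster 2): emphysema
  (0.52, 0.31), exacerbations (0.61, 0.44), unscheduled visits
  (0.53, 0.33), hypertension (0.39, 0.24), diabetes (0.17, 0.06);
* paired visits with transition counts (stay-1, stay-2, 1→mixed, 2→1) =
  (68, 40, 29, 26) over 163 subjects; *mixed* subjects carry 50% of
  both planted effect sets (the average of the two full profiles — the
  Cluster-1 side is included so its 6 proteins behave symmetrically);
  visit 2 is re-drawn with fresh noise and technical factors;
* a transfer cohort (47 subjects, 34/13) that re-plants a configured
  fraction (default 71/90) of the learning cohort's up-set plus fresh
  up-proteins to a total of 114, and 11 disjoint Cluster-1 proteins;
* a 50-subject healthy cohort with no planted structure.

Protein identities, baselines and effect sizes are drawn from a
per-scenario-family `layout_seed`, so the learning, paired and transfer
scenarios agree on which proteins carry signal; `seed` drives all
subject-level randomness.  Identical configuration and seed give
bit-identical output.

What the generator does *not* emulate: aptamer chemistry, limits of
detection, missing values, per-protein-per-plate batch interactions,
heteroskedastic or correlated noise, and effect-size distributions of
real disease signatures (the uniform range is an assumption chosen for
detectability at the default cohort sizes).  Passing recovery tests
therefore demonstrates correctness of the statistical machinery under
the planted model, not performance on real serum data.

## Numerical choices and degenerate inputs

* Variance-filter count uses `floor`; ties in SD break by column order.
* Ward merges break ties by smallest index (scipy behavior), making
  clustering deterministic for fixed input.
* Zero-variance panels (all subjects identical) raise rather than
  cluster; zero-variance proteins under the ordinary t are flagged with
  p = 1; prior fitting excludes non-positive sample variances.
* The trigamma inverse uses the standard Newton recurrence with
  closed-form guards for extreme arguments.
* BH q-values are clipped to [0, 1] and mapped back to input order;
  thresholding q < α reproduces the classic step-up rejection set.
* Strict inequalities everywhere in the significance rule (fold change
  exactly 1.5 or q exactly 0.05 is not significant).
* Fisher's two-sided p uses the probability-mass rule with a 1e-9
  relative tolerance when comparing table probabilities.

## Problem sizes

The packaged scenarios run the full pipeline in a few seconds each on a
single CPU (241×1305 learning cohort, 163×1305×2 paired cohort);
Monte-Carlo property checks in the test suite use 10–20 replicates at
these sizes or reduced panels, chosen to keep the whole suite under a
minute while leaving planted-recovery margins wide.
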