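# Methods

This note documents the models, parameter choices and numerical
conventions of `omicfuse`, and what the synthetic cohorts do and do not
establish about behaviour on real data.

## Synthetic cohorts

The generator emulates a two-modality plasma omics study of a type 2
diabetes cohort with a planted two-subgroup structure.

**Feature model.** Values are Gaussian on the log scale (log-normal
concentrations), with a per-feature baseline log-abundance drawn from
N(3, 1).  Within-block correlation comes from a single shared latent
factor per patient with loading `sqrt(rho)` (`noise_correlation`, default
0.2), so every feature has unit within-subgroup variance regardless of
rho.  The first `n_informative` features of each block are shifted by
`effect_size` SD units in subgroup 1 ("elevated" convention); placing
them first is deliberate so tests can check recovery by index.  All
matrices are returned on the log scale, which is the scale every
downstream stage operates on; `OmicsBlock.to_csv(concentrations=True)`
exponentiates for export.

**Cohort defaults** mirror the scale of the kind of study the pipeline
targets: 589 patients, blocks of 180 lipids and 1195 proteins, subgroup
proportions 0.465/0.535, age N(62, 10) years, 56.7% male, BMI
N(29.7, 4.6) kg/m², and a subgroup hazard ratio of 0.56.  Subgroup
assignment is deterministic largest-remainder allocation followed by a
seeded shuffle, so counts are exact and runs are bit-reproducible from
the seed.

**Survival.** Event times are exponential with hazard
`baseline_rate * HR^[g = 2]` (baseline 0.12/year), administratively
censored at `censor_time` (10 years).  A hazard ratio below 1 therefore
protects subgroup 2, matching the convention in which a Cox model reports
the second subgroup against the first.  The longitudinal generator
realizes each event as either a sustained insulin start or a pair of
qualifying high-HbA1c visits, on a twice-yearly visit grid (rounded to
1e-6 years so flag comparisons are exact); non-progressors get HbA1c
clipped below the 69 mmol/mol threshold.  Insulin-route events get
follow-up visits extending ~0.6 years past the start so the sustained-use
rule is decidable even near the censoring horizon.

**What this does not emulate:** real lipid/protein marginals and their
block-correlation structure, assay batch effects, missingness patterns,
covariate–subgroup confounding, or informative censoring.  Passing tests
demonstrate correctness and calibration of the algorithms under a clean
generative model, not performance on any particular clinical dataset.

## Preprocessing and distances

Complete-case filtering keeps the intersection of patients complete in
every block and in the age/sex/BMI covariates, in one canonical (sorted)
order.  Standardization uses the sample SD (n−1); zero-variance features
are a hard error rather than being silently dropped, because silent
dropping changes distances irreproducibly.  Distances are **squared**
Euclidean — the convention the scaled exponential kernel expects — and
this choice is recorded in every run manifest.

## SNF

The affinity kernel is the scaled exponential form with local scale
`eps_ij = (m_i + m_j + D_ij)/3` floored at 1e-12.  The defaults K = 20,
alpha = 5, T = 20 are the working values of the analysis this package
reimplements; note alpha = 5 is unusually large for this kernel family
(0.3–0.8 is common in the SNF literature) and flattens the kernel
considerably — the KNN-masked local kernel still carries the ordering
information, and the value is exposed as a configuration knob rather
than hard-coded.

In the fusion loop each view is symmetrized first and then renormalized
with the full-transition operator, so every intermediate is exactly
row-stochastic entering the next round (the reverse order would leave
row sums off by the symmetrization).  KNN ties break by stable index
order.  The fused matrix is the view average, symmetrized, with the
diagonal set to the row maximum so self-similarity stays maximal for
spectral clustering.  On the planted fixture the relative Frobenius delta
at T = 20 is ~1e-12.

## Clustering and model selection

Spectral clustering is the Ng–Jordan–Weiss variant: symmetric normalized
Laplacian, k smallest-eigenvalue eigenvectors, row-normalized embedding,
k-means with 50 restarts and a fixed seed; labels are renumbered by first
occurrence so the output is a pure function of (W, k, seed).  A graph
with more connected components than k, or a zero-degree node, is an
error.  Silhouette widths are computed from the similarity matrix via
`d = max(W) − W` (diagonal 0); singleton-cluster members get width 0.
`select_k` scans k in 2..10 (2..6 in the test fixtures, where larger k is
uninformative) and breaks silhouette ties toward smaller k.  For k = 2,
`orient_two_clusters` renames clusters so subgroup 1 is the one with the
higher overall standardized feature level, making effect directions
(e.g. hazard ratios) comparable across runs.

## Cluster-validation randomization test

Observed statistic: per cluster, the mean local clustering coefficient of
its members in the graph obtained by thresholding the fused similarities
at their 97.5th percentile (strictly-upper-triangle quantile, strict
inequality).  Nodes of degree < 2 have undefined coefficients and are
excluded from means; a cluster with no defined member scores 0.  The null
statistic is the model-level mean of cluster-mean coefficients from
re-running the full affinity → fusion → spectral (k fixed) → adjacency →
coefficient chain on randomized data; p-values use add-one smoothing and
the raw frequency is also reported.

**Null model choice.** Two randomizations are implemented.  Permuting the
off-diagonal entries of each distance matrix is the most literal
"randomized distance matrices", but it destroys metric structure that
even i.i.d. data possesses: on fully exchangeable noise cohorts the
observed top-quantile graph has mean local clustering ~0.10 against an
entry-permuted null of ~0.05, and about two thirds of noise clusters come
out "significant".  The package therefore defaults to permuting patients
independently **within every feature column** and recomputing distances:
this preserves each feature's marginal exactly, destroys all
patient-level structure, and makes the null chain statistically identical
to the observed chain under patient exchangeability — the test then
attains its nominal type-I error (measured false-positive rate ~5% at
p <= 0.05 across noise cohorts) while planted structure remains maximally
significant.  The entry-permutation null stays available behind
`null_model="entries"` for comparison with analyses that used it.

Calibration is assessed on cohorts with `effect_size = 0` **and**
`noise_correlation = 0`: a shared latent factor is genuine patient-level
structure which the test legitimately detects, so nominal calibration is
only meaningful under full exchangeability.  The calibration runs use 20
cohorts of 120 patients (blocks 40 + 80) at 200 randomizations each — a
scale at which the Monte-Carlo binomial band around 5% is informative.

## Association stage

Per-molecule logistic regressions (IRLS via GLM, max 100 iterations,
tolerance 1e-8) are marginal — one model per feature — with age, sex and
BMI as covariates, matching the convention of testing each molecule
separately.  Features are expected standardized so coefficients are
log-odds per SD.  Complete separation is detected as |coefficient| > 15
on that scale (or non-convergence) and flagged with the p-value set
missing.  BH adjustment is the standard step-up with monotonicity
enforcement; missing p-values are excluded and preserved.

The composite endpoint takes the earliest of (a) an insulin episode
sustained more than 6 months — an episode that ends without an explicit
stop time is credited only up to its last flagged visit — and (b) the
second of two qualifying HbA1c measurements (> 69 mmol/mol, >= 3 months
apart, both while on >= 2 non-insulin drugs), with the event at the
second measurement.  "Two qualifying measurements" rather than "more than
two" follows the endpoint literature this definition descends from; the
count is configurable (`min_qualifying`).  Thresholds are strict
inequalities.

Cox models use Efron tie handling (lifelines) by default; Breslow is
available via `ties="breslow"` (statsmodels PHReg).  A monotone partial
likelihood (all events in one group) is returned as a flagged
non-convergent result rather than a spurious estimate.  Overlap between
two patient labelings is scored per cluster pair by the one-sided
hypergeometric tail P(X >= intersect).

## ComDim (CCSWA)

Per component: saliences start at 1; iterate the dominant eigenvector t
of `G = sum_b lambda_b X_b X_b'` and the update `lambda_b = t' X_b X_b' t`
until the salience change falls below a tolerance **relative to the
salience scale** (1e-10; an absolute tolerance is unattainable in double
precision for wide blocks where lambda is numerically large), then
deflate `X_b <- (I − t t') X_b`.  Scores are unit-norm with the sign
fixed so the largest-magnitude entry is positive; explained fractions are
measured against the total squared Frobenius norm of the undeflated
blocks.  Block pre-normalization to unit Frobenius norm is available but
off by default.  Subgroup separation per component is Cohen's d with
pooled SD.

## Reporting and privacy-style aggregation

Betweenness centrality (unnormalized Brandes, via networkx) sizes nodes
of the thresholded network.  Group-mean aggregation emits per-feature
means only over consecutive canonical-order chunks of at least 5 patients
(remainder absorbed into the final chunk, so a cluster of 12 yields
chunks of 5 and 7), mirroring the non-disclosure constraint of federated
cohort databases; no emitted statistic ever covers fewer than `min_group`
patients.  Heatmap feature order comes from average-linkage hierarchical
clustering of row-z-scored chunk means and is written to file so figures
are reproducible.

## Problem sizes used in tests

The planted fixture is 300 patients with blocks of 60 and 120 features
(20% informative at 1.5 SD); randomization tests run 200 iterations and
calibration uses 20 noise cohorts of 120 patients; Cox recovery uses 50
replicates of 600 patients; association calibration uses 10 planted
cohorts plus 500 null features.  These sizes keep the whole suite at a
few minutes on one CPU while leaving Monte-Carlo bands tight enough for
the calibration claims to be meaningful.

## Known limitations

- The silhouette-from-similarity conversion `max(W) − W` is one of
  several reasonable conventions; values are comparable within a run,
  not across similarity scales.
- The spectral discretization (k-means) can in principle differ from
  rotation-based discretizations on near-degenerate eigengaps.
- The within-feature null conditions on feature marginals but not on
  inter-feature correlation; with strongly correlated features and no
  subgroup structure the test will (correctly) detect the correlation
  structure as non-exchangeability, which is a property of the statistic,
  not a bug of the implementation.
- ComDim components are extracted greedily; no variant (P-ComDim,
  path-ComDim) is implemented.
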