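# omicfuse

Unsupervised multi-omics patient subgrouping via Similarity Network Fusion
(SNF), with cluster validation, subgroup characterization and survival
modelling.

## The problem

Complex diseases such as type 2 diabetes progress very differently between
patients, and clinical variables alone capture that heterogeneity poorly.
A "bottom-up" alternative is to group patients purely from molecular
profiles: measure several omics modalities (for example a plasma
lipidomics panel and a proteomics panel) on the same cohort, build one
patient-similarity network per modality, fuse the networks, and look for
subgroups in the fused network.  The subgroups can then be characterized
molecularly (which lipids/proteins differ), clinically (covariates,
insulin-resistance surrogates) and prognostically (time until insulin
treatment is required).

`omicfuse` implements that entire workflow as a tested, reusable Python
library plus CLI, together with a synthetic-cohort generator so every
stage can be exercised and calibrated without access to patient-level
data (which, for the cohorts this kind of analysis targets, typically
lives behind non-disclosive federated infrastructure).

## The method

**Per-modality networks.** Each block `X_b` (patients x features) is
standardized per feature (mean 0, sample SD 1) and converted to squared
Euclidean distances `D`.  Similarities use the locally scaled exponential
kernel

```
W[i,j] = exp( -D[i,j] / (alpha * eps_ij) ),   eps_ij = (m_i + m_j + D[i,j]) / 3
```

with `m_i` the mean distance from patient i to its K nearest neighbours
(defaults K = 20, alpha = 5).

**Fusion.** Each view's full transition matrix `P_v` (row-stochastic,
diagonal 1/2) is diffused through its K-nearest-neighbour local kernel
`S_v`:

```
P_v  <-  S_v · mean_{u != v}(P_u) · S_v'
```

for T = 20 rounds, renormalizing and symmetrizing each round.  The fused
network is the view average with the diagonal set to the row maximum.

**Clustering and model choice.** Ng–Jordan–Weiss spectral clustering of
the fused network (symmetric normalized Laplacian, eigenvector embedding,
seeded k-means with 50 restarts); the number of clusters k in 2..10 is
chosen by the mean silhouette width computed directly from the similarity
matrix (dissimilarity `max(W) - W`).

**Cluster validation.** The fused network is thresholded at its 97.5th
similarity percentile into a binary graph and each cluster is scored by
its members' mean local clustering coefficient
`c_i = 2 t_i / (d_i (d_i - 1))`.  The null distribution re-runs the whole
chain on randomized data (by default permuting patients independently
within every feature, which preserves feature marginals and is exactly
calibrated under patient exchangeability); the empirical p-value per
cluster is `(1 + #{null >= observed}) / (1 + n_iter)`.

**Subgroup characterization.** Per molecule, a covariate-adjusted logistic
regression `logit P(subgroup 2) ~ feature + age + sex + BMI` with
Benjamini–Hochberg FDR control; a composite time-to-insulin endpoint
(insulin sustained > 6 months, or two HbA1c measurements > 69 mmol/mol at
least 3 months apart while on >= 2 non-insulin drugs); Cox proportional
hazards for the subgroup hazard ratio with the same covariates;
hypergeometric overlap enrichment against any external patient labelling;
and multiblock ComDim (CCSWA) extracting common patient scores with
per-block saliences as an independent view of the separation.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from omicfuse import (
    CohortSpec, SNFParams, SignificanceParams,
    generate_cohort, generate_survival_directly, standardize,
    pairwise_squared_distance, affinity_matrix, snf_fuse, select_k,
    cluster_significance, cox_ph, orient_two_clusters,
)

spec = CohortSpec(n_patients=300, block_sizes=(60, 120), n_informative=(12, 24),
                  effect_size=1.5, seed=42)
blocks, clinical = generate_cohort(spec)
std = [standardize(b) for b in blocks]
distances = [pairwise_squared_distance(b) for b in std]
params = SNFParams()          # K=20 neighbours, alpha=5, T=20 iterations
fused = snf_fuse([affinity_matrix(d, params) for d in distances], params)

assignment = select_k(fused, k_min=2, k_max=6, seed=42)
overall = np.hstack([b.values for b in std]).mean(axis=1)
labels = orient_two_clusters(assignment.labels, overall)
print(f"selected k = {assignment.k}")
print(f"mean silhouette width at k=2 = {assignment.silhouette_by_k[2]:.3f}")
print(f"ARI against planted subgroups = "
      f"{adjusted_rand_score(clinical['true_subgroup'], labels):.3f}")

sig = cluster_significance(distances, params, assignment,
                           SignificanceParams(n_iter=200, seed=7), blocks=std)
print("cluster p-values =", {c: round(p, 4) for c, p in sig.p_values.items()})

surv = generate_survival_directly(spec, clinical, np.random.default_rng(43))
cox = cox_ph(surv["time"], surv["event"], labels, clinical)
print(f"hazard ratio (subgroup 2 vs 1) = {cox.hazard_ratio:.2f} "
      f"[{cox.ci_low:.2f}, {cox.ci_high:.2f}], p = {cox.p_value:.1e}")
```

prints

```
selected k = 2
mean silhouette width at k=2 = 0.187
ARI against planted subgroups = 1.000
cluster p-values = {1: 0.005, 2: 0.005}
hazard ratio (subgroup 2 vs 1) = 0.57 [0.42, 0.78], p = 3.7e-04
```

The pipeline selects two subgroups by silhouette, recovers the planted
labels exactly, both clusters beat all 200 randomized models
(p = 1/201), and the Cox model recovers the generator's protective
hazard ratio of 0.56 for subgroup 2 (slower progression to insulin).

The same run is available from a shell:

```
omicfuse run-all --seed 42 --out run/
omicfuse report run/
```

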