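# Methods note

This note records the mathematical definitions, default parameters and
numerical conventions implemented in `woundstage`, including choices the
code had to make where a verbal description admits several readings.

## Data model

An expression dataset is a strictly positive linear-intensity tensor
indexed `(gene, timepoint, replicate)` with a mandatory unwounded
baseline at t = 0 h and at least three post-wounding timepoints
(`io_formats.ExpressionDataset`). Times are always hours. Datasets whose
biopsies pool a time window (e.g. a "1–3 day" group) carry explicit
intervals; the interval midpoint serves as the working timepoint
everywhere a scalar time is needed. Cross-species comparison goes through
a homologene table mapping `(species, symbol) → homologene id`; symbols
without a unique mapping are dropped (conservative).

## Quality filters

Filters run per dataset, in fixed order, each in a single pass (no
re-estimation of thresholds after removals):

1. **Multi-gene probe rows.** Rows whose identifier names several genes
   (`A//B`) are removed.
2. **Replicate consistency.** With replicate mean `G = mean_k G^k`, the
   percent relative error of replicate k is
   `S^k = |G^k − G| / G × 100`. Per timepoint, `r_avg` and `r_std` are
   the mean and population (divide-by-N) standard deviation of `S^k`
   pooled over **all** genes and replicates, and
   `r_thres = r_avg + 4·r_std`. A gene is removed iff its worst
   replicate error strictly exceeds `r_thres` at any timepoint. Strict
   inequality means the degenerate identical-replicates case (all
   errors = thresholds = 0) keeps every gene. Survivors are carried
   forward replicate-averaged.
3. **Repeated gene rows.** For several rows sharing one identifier, all
   pairwise Pearson correlations over timepoints are computed; the group
   is kept iff the maximum is ≥ 0.9 (inclusive), and then replaced by
   the mean of the best pair (ties resolved to the earliest rows in
   input order). Correlation is undefined — and such pairs are ignored —
   for fewer than 3 timepoints or constant rows; a group with only
   undefined pairs is dropped with a warning.
4. **Homologene duplicates.** After re-keying symbols to homologene ids,
   ids covering several rows are collapsed by the same rule.

The 4-SD multiplier and the 0.9 cutoff are arguments with these
defaults. A `FilterReport` records surviving-gene counts per step and
enforces monotone non-increase.

## Signature selection and temporal clustering

Per dataset, each gene's maximum observed fold change is
`ΔG = (I_max − I_min)/I_min` computed on the replicate-averaged linear
intensities over the full time course. The top k genes per dataset
(default k = 300; ties at the boundary broken lexicographically by gene
id so selection is deterministic) are intersected across all training
datasets; the sorted intersection is the signature.

In the reference dataset (by default the first training dataset), each
signature gene's **peak time** is the earliest timepoint at which its
replicate-averaged profile attains its maximum. Peak times are binned
into five half-open intervals (hours, `(low, high]`, with 0 belonging to
the first bin): `(0,18]`, `(18,48]`, `(48,96]`, `(96,132]`, `(132,∞)`.
The edges sit midway between the reference grid's sampling times, so on
an 8-point grid 0/6/12/24/72/120/168/240 h they implement the canonical
"peaks at ≤12 h / 24 h / 72 h / 120 h / >120 h" clustering while binning
arbitrary grids sensibly. Genes of other datasets inherit the reference
cluster.

## Embedding

For a biopsy at time t, replicate r, the mean cluster value of cluster i
is `J_i = mean over cluster-i genes of the linear intensity`; duplicate
rows of one gene are averaged first. The embedding coordinate is
`C_i = J_i / J_i(0)`. Two baseline policies exist: `per_replicate`
(default; each replicate normalized by its own t = 0 sample, making the
embedding invariant to per-replicate intensity scaling) and
`dataset_mean` (replicate-averaged baseline). Signature genes absent
from a dataset are excluded from the means, but every cluster must keep
at least one gene (error otherwise). By construction baselines embed to
`(1,1,1,1,1)` and any common positive rescaling of intensities leaves
embeddings unchanged.

## Reference stage labels

Unless overridden per (dataset, time), labels follow the canonical acute
timing: hemostasis for t < 12 h, inflammation for 12 ≤ t ≤ 48 h,
proliferation for 48 < t ≤ 168 h (through day 7 inclusive), remodeling
afterwards; interval-sampled biopsies are labeled by their interval
midpoint, and t = 0 baselines are hemostasis.

## Cascaded SVM

Three binary maximum-margin classifiers applied in fixed order, each in
a stated coordinate subspace:

| step | subspace | kernel | decision |
|---|---|---|---|
| 1 | {C3, C4, C5} | linear | inflammation vs rest |
| 2 | {C1, C5} | polynomial | hemostasis vs proliferation/remodeling |
| 3 | {C2, C5} | polynomial | proliferation vs remodeling |

Step 2 trains only on non-inflammation points, step 3 only on
proliferation/remodeling points. Polynomial kernels are
`(γ·x·y + c₀)^d` with defaults d = 3, c₀ = 1, γ = 1, box constraint
C = 1 and **no** feature standardization — the embeddings are already
ratio-normalized. All settings are configurable
(`stager.SvmHyperParams`). Fitting is delegated to scikit-learn's `SVC`,
after which a model is reduced to support vectors, dual coefficients and
intercept; prediction is a pure function of those stored parameters, so
models round-trip exactly through JSON. Degenerate single-class training
sets yield an explicit constant classifier with a warning; an empty
step-3 training set is an error.

Training uses one replicate (default replicate 1) of every timepoint of
each training dataset; evaluation covers the remaining replicates plus
any held-out datasets, reported as per-(dataset, time) predicted-stage
counts.

## Synthetic cohort generator

`synthdata.generate_cohort` emulates the structure above on three
default grids: a dense 8-point reference course
(0–240 h, mouse), a sparse 4-point course (0/2/72/336 h, mouse) and an
interval-sampled human course (windows 0, 24–72, 96–168, 192–336 h),
three replicates each. Defaults: 10 genes per cluster (50 signature
genes), 20 nuisance genes, log-noise SD σ = 0.05.

* **Archetypes.** Five positive temporal profiles, one per cluster:
  cluster 1 decays from its baseline maximum with a shallow late
  recovery; clusters 2–5 are log-time Gaussian bumps peaking near 24,
  72, 120 and 240 h, with asymmetric rise/decay widths and a doubled
  amplitude for the 72 h (inflammatory) archetype. Per gene, the dynamic
  part is jittered by a uniform amplitude factor and scaled to a random
  baseline intensity.
* **Noise.** Multiplicative replicate noise `exp(u)`,
  `u ~ U(−√3σ, +√3σ)` (standard deviation σ). The bounded support is
  deliberate: no unplanted replicate can cross the 4-SD consistency
  threshold, so the generator's outlier registry is *exhaustive* ground
  truth — the filter's removals can be asserted to equal the planted
  set exactly, not merely to contain it.
* **Planted structure.** Extreme single-replicate outliers (×10, by
  default only on nuisance genes so downstream counts stay fixed),
  correlated duplicate rows of signature genes, decoy duplicate rows of
  nuisance genes (a shuffled permutation of the gene's own profile —
  uncorrelated in expectation, same low dynamic range), second human
  symbols sharing a homologene id, and multi-gene probe rows. Every
  planted feature is recorded in a `CohortTruth` registry.

The generator reproduces what the pipeline *assumes* — separable stage
structure, cluster-coherent dynamics, well-behaved noise. It does not
emulate platform batch effects, probe saturation, missing values,
between-subject heterogeneity or chronic-wound deviations from the
canonical trajectory; conclusions about robustness to those must come
from real data.

## Robustness experiments and bookkeeping

`evaluation` provides: training-replicate sensitivity (retrain on every
one-replicate-per-dataset combination, score the constant held-out pool,
report worst case and matched/mixed groups); gene-subset sensitivity
(re-embed from random signature subsets covering all five clusters,
model fixed; a subset size equal to the shared gene pool admits exactly
one subset, hence SD = 0, and sizes below 5 are infeasible); embedding
augmentation by multiplicative jitter; and a degree × box-constraint
sweep used when reproducing published results whose kernel settings were
not reported. Accuracy SDs use the population convention.

The module also encodes the sampling designs of the five public
acute-wound GEO series the method targets (8+4+4 training timepoints × 3
replicates; two single-replicate external test sets totalling 37
biopsies), from which the training/test arithmetic — 16 training points,
32 held-out replicate points, 69 test points, 85 points in all — is
recomputed rather than hard-coded.

## Numerical conventions and limitations

* All statistics on linear intensities; logs are display-only.
* Population (ddof = 0) SDs throughout; per-timepoint thresholds pool
  3 × n_genes values, so the sample/population distinction is
  negligible but fixed for reproducibility.
* Ties: earliest timepoint wins peak-time ties; earliest row order wins
  duplicate-pair correlation ties; lexicographic gene-id order breaks
  top-k boundary ties. These make every pipeline stage deterministic.
* The consistency filter needs ≥ 2 replicates; single-replicate
  (test-only) datasets skip it and enter embedding after multi-gene row
  removal and harmonization only.
* Sensitivity of the stage boundaries: biopsies near a stage transition
  (e.g. 12 h, onset of inflammation) are the typical misclassifications;
  the cascade's soft margin may sacrifice an isolated boundary point
  even when it is linearly separable.
* The default synthetic problem sizes (50 signature genes, 20 nuisance
  genes, three datasets) are this package's choice of a tractable test
  condition; the selection rank k = 300 default targets genome-scale
  inputs and is set to the signature size in generated configurations.
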