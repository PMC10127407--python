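# woundstage

Wound-healing stage classification from transcriptomic time courses.

## The problem

Acute wound repair passes through four canonical, partially overlapping
stages — hemostasis, inflammation, proliferation and remodeling — and
chronic wounds stall between them. Standard clinical assessment judges the
stage visually; gene expression profiling of a wound-edge biopsy offers an
objective alternative. The difficulty is that raw microarray time courses
are noisy, come from different species, platforms and time grids, and have
tens of thousands of genes per sample.

This package implements a complete pipeline that reduces a biopsy's
transcriptome to a point in a 5-dimensional "cluster space" and classifies
its healing stage there:

1. **Quality filtering** (per dataset): drop multi-gene probe rows; drop
   genes with an extreme replicate outlier (percent relative error above
   the per-timepoint threshold `r_avg + 4·r_std`, estimated over all genes
   and replicates jointly); collapse repeated gene rows and cross-species
   homologene duplicates, keeping only groups whose best pair correlates at
   Pearson ≥ 0.9 (retained row = mean of that pair).
2. **Signature selection**: per dataset, rank genes by maximum observed
   fold change `ΔG = (I_max − I_min)/I_min` on linear intensities, take the
   top k (default 300), and intersect the sets across all training
   datasets. Genes strongly regulated in *every* dataset form the wound
   signature.
3. **Temporal clustering**: in a reference time course, each signature
   gene's peak time (earliest maximum of its replicate-averaged profile)
   assigns it to one of five clusters — early/baseline-high, ~24 h, ~72 h,
   ~120 h and late peaking.
4. **Embedding**: a biopsy at time *t* becomes the 5-vector of normalized
   mean cluster values `J_i(t)/J_i(0)`, where `J_i` is the mean linear
   intensity of cluster *i*'s genes and the denominator is the unwounded
   (t = 0) baseline. Healing traces a closed trajectory through this space;
   an unwounded biopsy sits at `(1,1,1,1,1)`.
5. **Staging**: a cascade of three binary SVMs — linear on `{C3,C4,C5}`
   (inflammation vs rest), then polynomial on `{C1,C5}` (hemostasis vs
   later stages), then polynomial on `{C2,C5}` (proliferation vs
   remodeling). Polynomial kernels default to degree 3, offset 1, unit box
   constraint, no feature standardization.

A seeded synthetic-cohort generator reproduces the statistical structure
the pipeline assumes (heterogeneous time grids, bounded multiplicative
replicate noise, planted outliers, duplicate/decoy rows, a mouse↔human
homologene map) together with a ground-truth registry, so every pipeline
stage can be tested against known answers. `woundstage.evaluation` adds
robustness experiments (training-replicate sensitivity, gene-subset
sensitivity, hyperparameter sweeps) and the study-design bookkeeping of
the public acute-wound microarray cohort the method targets.

See `docs/methods.md` for the precise definitions and numerical choices.

## Worked example

Simulate a three-dataset cohort and run the full pipeline:

```text
$ woundstage simulate --seed 0 --out demo
demo
$ woundstage run --config demo/config.yaml --out demo/results
...
synth_human_burn: initial -> 88 genes
synth_human_burn: drop_multigene_rows -> 85 genes
synth_human_burn: replicate_consistency -> 85 genes
synth_human_burn: collapse_repeated_genes -> 70 genes
synth_human_burn: homologene_harmonization -> 65 genes
synth_human_burn: collapse_homologene_duplicates -> 65 genes
stage: signature selection (top_k=50)
selected 50 signature genes
stage: clustering on reference synth_mouse_surgical
stage: embedding
stage: training (replicate 1)
stage: evaluation (16 train, 32 test points)
evaluation: 30/32 correct
30/32 test points correct
```

The output directory contains the per-dataset filter reports, the
signature with cluster assignments, all biopsy embeddings, the serialized
stage model (`model.json`, reloadable with `StageModel.from_json`), the
per-timepoint evaluation table and a JSON summary:

```text
$ head -4 demo/results/evaluation.tsv
dataset	time_h	assigned_stage	hemostasis	inflammation	proliferation	remodeling	n_total	n_errors
synth_human_burn	0.0	hemostasis	2	0	0	0	2	0
synth_human_burn	48.0	inflammation	0	2	0	0	2	0
synth_human_burn	132.0	proliferation	0	0	2	0	2	0
```

The two errors are the 12 h biopsies of the densely sampled mouse dataset,
predicted hemostasis instead of inflammation — a stage-boundary point
where the inflammatory signal is only beginning to rise.

The same run decomposes into composable subcommands
(`filter → select → cluster → embed → train → evaluate`), which produce
byte-identical artifacts; `predict` applies a saved model to new
embeddings and `sensitivity` runs the robustness experiments.

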