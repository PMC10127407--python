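"""End-to-end orchestration: filter -> select -> cluster -> embed -> stage.

:func:`run_pipeline` wires the per-module operations together exactly the
way the CLI subcommands compose, so chaining subcommands by hand and the
one-shot pipeline produce identical artifacts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError
from .filtering import (
    DEFAULT_CORR_THRESHOLD,
    DEFAULT_SD_MULTIPLIER,
    drop_multigene_rows,
    run_filter_pipeline,
)
from .io_formats import (
    ExpressionDataset,
    OrthologMap,
    harmonize_to_homologene,
    read_expression_table,
    read_ortholog_map,
)
from .signature import (
    DEFAULT_CLUSTER_BINS_H,
    DEFAULT_TOP_K,
    GeneSignature,
    assign_clusters,
    embed_biopsies,
    embeddings_to_frame,
    select_signature,
)
from .stager import (
    EvaluationResult,
    StageLabel,
    StageModel,
    SvmHyperParams,
    evaluate_predictions,
    label_points,
    train_stager,
)

logger = logging.getLogger(__name__)


@dataclass
class DatasetEntry:
    path: str
    dataset_id: str
    species: str
    role: str = "train"  # train | test


@dataclass
class PipelineConfig:
    """Everything needed for one end-to-end run.

    All method constants are named defaults: the 0.9 duplicate-correlation
    cutoff, the 4-SD replicate-outlier multiplier, the top-300 fold-change
    rank, the five peak-time bins, and the cascade kernel settings.
    """

    datasets: list[DatasetEntry]
    ortholog_map: str | None = None
    reference: str | None = None  # defaults to first training dataset
    corr_threshold: float = DEFAULT_CORR_THRESHOLD
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER
    top_k: int = DEFAULT_TOP_K
    cluster_bins_h: tuple = DEFAULT_CLUSTER_BINS_H
    stager: SvmHyperParams = field(default_factory=SvmHyperParams)
    baseline_policy: str = "per_replicate"
    train_replicate: int = 1
    stage_overrides: dict[tuple[str, float], StageLabel] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(str(path)))

        def resolve(p):
            return p if os.path.isabs(p) else os.path.join(base, p)

        entries = [
            DatasetEntry(
                path=resolve(d["path"]),
                dataset_id=d.get("dataset_id")
                or os.path.splitext(os.path.basename(d["path"]))[0],
                species=d.get("species", "unknown"),
                role=d.get("role", "train"),
            )
            for d in raw.get("datasets", [])
        ]
        overrides = {
            (o["dataset"], float(o["time_h"])): StageLabel(o["stage"])
            for o in raw.get("stage_overrides", [])
        }
        bins = raw.get("cluster_bins_h")
        return cls(
            datasets=entries,
            ortholog_map=(
                resolve(raw["ortholog_map"]) if raw.get("ortholog_map") else None
            ),
            reference=raw.get("reference"),
            corr_threshold=float(raw.get("corr_threshold", DEFAULT_CORR_THRESHOLD)),
            sd_multiplier=float(raw.get("sd_multiplier", DEFAULT_SD_MULTIPLIER)),
            top_k=int(raw.get("top_k", DEFAULT_TOP_K)),
            cluster_bins_h=(
                tuple(tuple(float(x) for x in b) for b in bins)
                if bins
                else DEFAULT_CLUSTER_BINS_H
            ),
            stager=SvmHyperParams(**raw.get("stager", {})),
            baseline_policy=raw.get("baseline_policy", "per_replicate"),
            train_replicate=int(raw.get("train_replicate", 1)),
            stage_overrides=overrides,
            seed=int(raw.get("seed", 0)),
        )

    def validate_paths(self) -> None:
        missing = [d.path for d in self.datasets if not os.path.exists(d.path)]
        if self.ortholog_map and not os.path.exists(self.ortholog_map):
            missing.append(self.ortholog_map)
        if missing:
            raise ConfigurationError(f"missing input files: {missing}")
        if not any(d.role == "train" for d in self.datasets):
            raise ConfigurationError("at least one training dataset required")


@dataclass
class PipelineResult:
    reports: dict
    signature: GeneSignature
    points_by_dataset: dict
    model: StageModel
    evaluation: EvaluationResult


def prepare_for_embedding(
    dataset: ExpressionDataset, ortholog_map: OrthologMap | None
) -> ExpressionDataset:
    """Multi-gene row removal plus homologene harmonization for embedding."""
    ds = drop_multigene_rows(dataset)
    if ortholog_map is not None:
        ds = harmonize_to_homologene(ds, ortholog_map)
    return ds


def run_pipeline_data(
    datasets: list[ExpressionDataset],
    roles: dict[str, str],
    ortholog_map: OrthologMap | None,
    config: PipelineConfig,
) -> PipelineResult:
    """Run on in-memory datasets; ``roles`` maps dataset id to train/test."""
    train_ids = [d.dataset_id for d in datasets if roles[d.dataset_id] == "train"]
    if not train_ids:
        raise ConfigurationError("no training datasets")
    reference_id = config.reference or train_ids[0]

    logger.info("stage: filtering (%d datasets)", len(datasets))
    matrices, reports = {}, {}
    for ds in datasets:
        if roles[ds.dataset_id] != "train":
            continue
        matrix, report, _ = run_filter_pipeline(
            ds,
            ortholog_map,
            corr_threshold=config.corr_threshold,
            sd_multiplier=config.sd_multiplier,
        )
        matrices[ds.dataset_id] = matrix
        reports[ds.dataset_id] = report

    logger.info("stage: signature selection (top_k=%d)", config.top_k)
    genes = select_signature(
        {ds_id: matrices[ds_id] for ds_id in train_ids}, top_k=config.top_k
    )
    logger.info("selected %d signature genes", len(genes))

    logger.info("stage: clustering on reference %s", reference_id)
    sig = assign_clusters(
        matrices[reference_id],
        genes,
        bins=config.cluster_bins_h,
        reference_dataset_id=reference_id,
    )

    logger.info("stage: embedding")
    points_by_dataset = {}
    for ds in datasets:
        prepared = prepare_for_embedding(ds, ortholog_map)
        pts = embed_biopsies(prepared, sig, baseline_policy=config.baseline_policy)
        label_points(pts, overrides=config.stage_overrides or None)
        points_by_dataset[ds.dataset_id] = pts

    logger.info("stage: training (replicate %d)", config.train_replicate)
    train_points = [
        p
        for ds_id in train_ids
        for p in points_by_dataset[ds_id]
        if p.replicate == config.train_replicate
    ]
    model = train_stager(train_points, hyper=config.stager, seed=config.seed)

    test_points = [
        p
        for ds_id, pts in points_by_dataset.items()
        for p in pts
        if roles[ds_id] != "train" or p.replicate != config.train_replicate
    ]
    logger.info(
        "stage: evaluation (%d train, %d test points)",
        len(train_points),
        len(test_points),
    )
    evaluation = evaluate_predictions(model, test_points)
    logger.info(
        "evaluation: %d/%d correct",
        evaluation.n_total - evaluation.n_errors,
        evaluation.n_total,
    )
    return PipelineResult(
        reports=reports,
        signature=sig,
        points_by_dataset=points_by_dataset,
        model=model,
        evaluation=evaluation,
    )


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """File-based run: read inputs, execute, write all artifacts."""
    config.validate_paths()
    datasets = [
        read_expression_table(e.path, dataset_id=e.dataset_id, species=e.species)
        for e in config.datasets
    ]
    roles = {e.dataset_id: e.role for e in config.datasets}
    ortholog_map = (
        read_ortholog_map(config.ortholog_map) if config.ortholog_map else None
    )
    result = run_pipeline_data(datasets, roles, ortholog_map, config)

    os.makedirs(out_dir, exist_ok=True)
    for ds_id, report in result.reports.items():
        report.to_tsv(os.path.join(out_dir, f"filter_report_{ds_id}.tsv"))
    result.signature.to_tsv(os.path.join(out_dir, "signature.tsv"))
    all_points = [p for pts in result.points_by_dataset.values() for p in pts]
    embeddings_to_frame(all_points).to_csv(
        os.path.join(out_dir, "embeddings.tsv"), sep="\t", index=False
    )
    result.model.to_json(os.path.join(out_dir, "model.json"))
    result.evaluation.table.to_csv(
        os.path.join(out_dir, "evaluation.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "summary.json"), "w", encoding="utf-8") as fh:
        json.dump(
            {
                "n_signature_genes": len(result.signature.genes),
                "n_test_points": result.evaluation.n_total,
                "n_errors": result.evaluation.n_errors,
                "accuracy": result.evaluation.accuracy,
                "filter_reports": {
                    ds: report.counts() for ds, report in result.reports.items()
                },
            },
            fh,
            indent=1,
        )
    return result
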