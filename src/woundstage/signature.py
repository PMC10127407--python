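"""Gene-signature selection, temporal clustering and biopsy embedding.

A biopsy's transcriptomic state is summarized by five *normalized mean
cluster values*: genes of the signature are grouped into five clusters by
the time their expression peaks in a reference time course, the linear
intensities of each cluster's genes are averaged per biopsy
(``J_i = mean_k g_k(t_i)``) and divided by the same quantity in the
unwounded baseline (``J_i / J_0``).  Healing then traces a closed
trajectory through this 5-dimensional space, and stages occupy separable
regions of it.

Signature genes are those with high maximum observed fold change
``(I_max - I_min) / I_min`` in *every* dataset: per dataset the top-k
(default 300) genes by fold change are taken and the sets intersected.
All computations use linear-scale intensities; log transforms are a
display concern only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    BaselineError,
    ClusterUnrepresentedError,
    MembershipError,
    PositivityError,
    WoundStageError,
)
from .io_formats import ExpressionDataset

logger = logging.getLogger(__name__)

N_CLUSTERS = 5
DEFAULT_TOP_K = 300

#: Half-open peak-time bins (low, high] in hours; the first bin includes 0.
#: Edges sit midway between the reference grid's sampling times
#: (12|24, 24|72, 72|120, 120|168 h), so that on that grid they reproduce
#: the canonical 0-12 h / 24 h / 72 h / 120 h / >120 h rule while binning
#: arbitrary grids sensibly.
DEFAULT_CLUSTER_BINS_H: tuple[tuple[float, float], ...] = (
    (0.0, 18.0),
    (18.0, 48.0),
    (48.0, 96.0),
    (96.0, 132.0),
    (132.0, float("inf")),
)


def max_fold_change(series) -> float:
    """Maximum observed fold change (I_max - I_min) / I_min of a series."""
    values = np.asarray(series, dtype=float)
    if values.size < 2:
        raise WoundStageError("fold change needs at least two timepoints")
    if not np.all(values > 0):
        raise PositivityError("fold change requires strictly positive values")
    vmin = values.min()
    return float((values.max() - vmin) / vmin)


def cluster_for_time(t: float, bins=DEFAULT_CLUSTER_BINS_H) -> int:
    """1-based cluster index of the bin containing peak time ``t``."""
    for c, (low, high) in enumerate(bins, start=1):
        if (t == 0 and low == 0) or (low < t <= high):
            return c
    raise WoundStageError(f"peak time {t} h not covered by cluster bins")


@dataclass
class GeneSignature:
    """Signature genes with temporal-cluster labels and reference peak times."""

    genes: list[str]
    cluster_of: dict[str, int]
    peak_time_h: dict[str, float]
    reference_dataset_id: str
    cluster_bins_h: tuple[tuple[float, float], ...] = DEFAULT_CLUSTER_BINS_H

    def __post_init__(self) -> None:
        for g in self.genes:
            c = self.cluster_of[g]
            low, high = self.cluster_bins_h[c - 1]
            t = self.peak_time_h[g]
            if not ((t == 0 and low == 0) or (low < t <= high)):
                raise WoundStageError(
                    f"peak time {t} h of gene {g} outside its cluster bin {c}"
                )

    def members(self, cluster: int) -> list[str]:
        return [g for g in self.genes if self.cluster_of[g] == cluster]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("homologene_id\tcluster\tpeak_time_h\n")
            for g in self.genes:
                fh.write(f"{g}\t{self.cluster_of[g]}\t{self.peak_time_h[g]!r}\n")

    @classmethod
    def from_tsv(cls, path, reference_dataset_id: str = "") -> "GeneSignature":
        genes, clusters, peaks = [], {}, {}
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                g, c, t = line.rstrip("\n").split("\t")
                genes.append(g)
                clusters[g] = int(c)
                peaks[g] = float(t)
        return cls(genes, clusters, peaks, reference_dataset_id)


@dataclass
class BiopsyPoint:
    """One biopsy embedded as a 5-vector of normalized mean cluster values."""

    dataset_id: str
    replicate: int
    time_h: float
    embedding: np.ndarray
    time_interval_h: tuple[float, float] | None = None
    assigned_stage: object | None = None
    genes_per_cluster: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=float)
        if self.embedding.shape != (N_CLUSTERS,):
            raise WoundStageError("embedding must be a 5-vector")
        if not np.all(self.embedding > 0):
            raise PositivityError("embedding entries must be positive")


def select_signature(
    datasets: dict[str, pd.DataFrame], top_k: int = DEFAULT_TOP_K
) -> list[str]:
    """Intersect per-dataset top-k fold-change gene sets.

    ``datasets`` maps dataset id to a replicate-averaged gene x timepoint
    matrix with a unique gene index.  Ties at the top-k boundary are
    broken lexicographically by gene id so the selection is deterministic.
    Returns the sorted intersection.
    """
    if len(datasets) < 2:
        raise WoundStageError("signature selection needs at least two datasets")
    selected: list[set[str]] = []
    for ds_id in sorted(datasets):
        matrix = datasets[ds_id]
        if matrix.index.has_duplicates:
            raise WoundStageError(
                f"{ds_id}: gene index must be unique before signature selection"
            )
        dg = matrix.apply(max_fold_change, axis=1)
        if len(dg) < top_k:
            logger.warning(
                "%s: only %d genes available for top-%d selection",
                ds_id,
                len(dg),
                top_k,
            )
        order = sorted(dg.index, key=lambda g: (-dg[g], g))
        selected.append(set(order[:top_k]))
    return sorted(set.intersection(*selected))


def assign_clusters(
    reference: pd.DataFrame,
    genes,
    bins=DEFAULT_CLUSTER_BINS_H,
    reference_dataset_id: str = "",
) -> GeneSignature:
    """Cluster signature genes by expression peak time in a reference matrix.

    The peak time is the earliest timepoint at which the replicate-averaged
    intensity attains its row maximum (ties resolved to the earliest).
    Genes of other datasets inherit the reference cluster regardless of
    their own dynamics.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in reference.index]
    if missing:
        raise MembershipError(f"genes absent from reference dataset: {missing}")
    times = np.asarray(reference.columns, dtype=float)
    cluster_of: dict[str, int] = {}
    peak_of: dict[str, float] = {}
    for g in genes:
        row = np.asarray(reference.loc[g], dtype=float)
        peak = float(times[int(np.argmax(row))])  # argmax -> earliest maximum
        peak_of[g] = peak
        cluster_of[g] = cluster_for_time(peak, bins)
    return GeneSignature(
        genes=genes,
        cluster_of=cluster_of,
        peak_time_h=peak_of,
        reference_dataset_id=reference_dataset_id,
        cluster_bins_h=tuple(tuple(b) for b in bins),
    )


def _mean_over_duplicates(dataset: ExpressionDataset) -> tuple[list[str], np.ndarray]:
    """Unique gene ids with intensities averaged over duplicate rows."""
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(dataset.gene_ids):
        if g not in groups:
            order.append(g)
        groups.setdefault(g, []).append(i)
    data = np.stack(
        [dataset.intensities[groups[g]].mean(axis=0) for g in order]
    )
    return order, data


def embed_biopsies(
    dataset: ExpressionDataset,
    signature: GeneSignature,
    baseline_policy: str = "per_replicate",
) -> list[BiopsyPoint]:
    """Embed every (timepoint, replicate) biopsy of a dataset.

    Per cluster, ``J`` is the arithmetic mean of the linear intensities of
    the cluster's genes available in this dataset; the embedding divides
    ``J`` by its unwounded-baseline value ``J_0``.  Under the default
    ``per_replicate`` policy each replicate is normalized by its own t=0
    sample; ``dataset_mean`` uses the replicate-averaged baseline.
    Signature genes missing from the dataset are silently excluded, but
    every cluster must keep at least one gene.
    """
    if baseline_policy not in {"per_replicate", "dataset_mean"}:
        raise WoundStageError(f"unknown baseline policy {baseline_policy!r}")
    if dataset.timepoints_h[0] != 0:
        raise BaselineError("dataset has no t=0 baseline biopsy")
    gene_ids, tensor = _mean_over_duplicates(dataset)
    pos = {g: i for i, g in enumerate(gene_ids)}
    members: list[list[int]] = []
    for c in range(1, N_CLUSTERS + 1):
        idx = [pos[g] for g in signature.members(c) if g in pos]
        if not idx:
            raise ClusterUnrepresentedError(
                f"{dataset.dataset_id}: cluster {c} unrepresented"
            )
        members.append(idx)
    genes_per_cluster = tuple(len(idx) for idx in members)
    if any(n == 0 for n in genes_per_cluster):  # pragma: no cover - guarded above
        raise ClusterUnrepresentedError("empty cluster")
    n_missing = len(signature.genes) - sum(genes_per_cluster)
    if n_missing:
        logger.info(
            "%s: %d of %d signature genes unavailable",
            dataset.dataset_id,
            n_missing,
            len(signature.genes),
        )

    # J tensor: (cluster, time, replicate)
    j = np.stack([tensor[idx].mean(axis=0) for idx in members])
    if baseline_policy == "per_replicate":
        j0 = j[:, 0, :]  # (cluster, replicate)
    else:
        j0 = np.repeat(j[:, 0, :].mean(axis=1)[:, None], dataset.n_replicates, axis=1)
    points: list[BiopsyPoint] = []
    for jt, t in enumerate(dataset.timepoints_h):
        for k in range(dataset.n_replicates):
            interval = (
                dataset.time_intervals_h[jt]
                if dataset.time_intervals_h is not None
                else None
            )
            points.append(
                BiopsyPoint(
                    dataset_id=dataset.dataset_id,
                    replicate=k + 1,
                    time_h=float(t),
                    time_interval_h=interval,
                    embedding=j[:, jt, k] / j0[:, k],
                    genes_per_cluster=genes_per_cluster,
                )
            )
    return points


def embeddings_to_frame(points: list[BiopsyPoint]) -> pd.DataFrame:
    """Tabular view of embeddings (dataset, time_h, replicate, C1..C5, stage)."""
    rows = []
    for p in points:
        row = {
            "dataset": p.dataset_id,
            "time_h": p.time_h,
            "replicate": p.replicate,
        }
        for c in range(N_CLUSTERS):
            row[f"C{c + 1}"] = p.embedding[c]
        row["assigned_stage"] = (
            str(p.assigned_stage) if p.assigned_stage is not None else ""
        )
        rows.append(row)
    return pd.DataFrame(rows)
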