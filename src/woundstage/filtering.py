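"""Quality filters for replicate-resolved expression time courses.

Four procedures are applied per dataset, in order:

1. **Multi-gene probe rows** — rows whose identifier contains ``//``
   (one probe hybridizing several transcripts) are removed.
2. **Replicate consistency** — for each replicate ``k`` the percent
   relative error ``S^k = |G^k - G| / G * 100`` against the replicate
   mean ``G`` is computed; per timepoint a threshold
   ``r_thres = r_avg + 4 * r_std`` is estimated over all genes and
   replicates jointly, and any gene whose worst replicate error exceeds
   the threshold (strictly) at any timepoint is discarded.  Survivors are
   carried forward as the replicate-averaged matrix.
3. **Repeated gene rows** — multiple rows for one gene are kept only if
   at least one pair correlates (Pearson, over timepoints) at or above
   0.9; the retained row is the mean of the best-correlated pair.
4. **Homologene duplicates** — the same correlation rule applied to
   several symbols sharing one homologene id after cross-species
   harmonization.

Thresholds (the 4-SD multiplier, the 0.9 correlation cutoff) are
arguments with those defaults.  All filters are single-pass: thresholds
are estimated once from the full matrix, not re-estimated after removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import PositivityError, WoundStageError
from .io_formats import (
    MULTIGENE_DELIMITER,
    ExpressionDataset,
    FilterReport,
    OrthologMap,
    harmonize_to_homologene,
)

logger = logging.getLogger(__name__)

DEFAULT_CORR_THRESHOLD = 0.9
DEFAULT_SD_MULTIPLIER = 4.0


@dataclass
class ReplicateConsistencyStats:
    """Per-timepoint relative-error statistics and per-gene worst errors.

    ``r_std`` uses the population (divide-by-N) convention; with
    ``3 * n_genes`` entries per column the distinction from the sample
    convention is negligible, but it must be fixed for reproducibility.
    """

    timepoints_h: np.ndarray
    r_avg: np.ndarray
    r_std: np.ndarray
    r_thres: np.ndarray
    s_max: pd.DataFrame  # gene x timepoint max percent relative error


def drop_multigene_rows(
    dataset: ExpressionDataset, report: FilterReport | None = None
) -> ExpressionDataset:
    """Remove rows whose gene id names several genes (``A//B//C``)."""
    keep = np.array(
        [MULTIGENE_DELIMITER not in g for g in dataset.gene_ids], dtype=bool
    )
    out = dataset.subset_genes(keep)
    if out.n_genes == 0:
        logger.warning("%s: all rows were multi-gene rows", dataset.dataset_id)
    if report is not None:
        report.add("drop_multigene_rows", out.n_genes)
    return out


def replicate_consistency_filter(
    dataset: ExpressionDataset,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, ReplicateConsistencyStats]:
    """Drop genes with an extreme replicate outlier; return averaged matrix.

    Removal uses strict inequality, so in the degenerate case of identical
    replicates (all errors and thresholds zero) every gene is kept.
    """
    if dataset.n_replicates < 2:
        raise WoundStageError("consistency filter requires >=2 replicates")
    tensor = dataset.intensities  # (gene, time, rep)
    mean = tensor.mean(axis=2)
    if not np.all(mean > 0):
        raise PositivityError("zero mean intensity encountered")
    rel_err = np.abs(tensor - mean[:, :, None]) / mean[:, :, None] * 100.0
    r_avg = rel_err.mean(axis=(0, 2))
    r_std = rel_err.std(axis=(0, 2))  # population SD
    r_thres = r_avg + sd_multiplier * r_std
    s_max = rel_err.max(axis=2)
    removed = (s_max > r_thres[None, :]).any(axis=1)
    stats = ReplicateConsistencyStats(
        timepoints_h=dataset.timepoints_h.copy(),
        r_avg=r_avg,
        r_std=r_std,
        r_thres=r_thres,
        s_max=pd.DataFrame(
            s_max,
            index=pd.Index(dataset.gene_ids, name="gene"),
            columns=dataset.timepoints_h,
        ),
    )
    averaged = pd.DataFrame(
        mean[~removed],
        index=pd.Index(
            [g for g, r in zip(dataset.gene_ids, removed) if not r], name="gene"
        ),
        columns=dataset.timepoints_h,
    )
    if report is not None:
        report.add("replicate_consistency", len(averaged))
    return averaged, stats


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson correlation, or None when undefined (short or constant rows)."""
    if len(x) < 3:
        return None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def _collapse_duplicate_rows(
    matrix: pd.DataFrame,
    corr_threshold: float,
    step_name: str,
    restrict_to: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Collapse groups of rows sharing an index id by best-correlated pair.

    Groups with a single row pass through.  For k >= 2 rows all pairwise
    Pearson correlations over timepoints are computed; if the maximum is
    at or above ``corr_threshold`` the group is replaced by the mean of
    the maximal pair (ties broken by earliest row order), otherwise the
    id is dropped.  ``restrict_to`` limits which ids are treated as
    collapsible groups; other duplicated ids pass through untouched.
    """
    values = matrix.to_numpy()
    ids = list(matrix.index)
    first_pos: dict[str, int] = {}
    groups: dict[str, list[int]] = {}
    for i, gid in enumerate(ids):
        first_pos.setdefault(gid, i)
        groups.setdefault(gid, []).append(i)

    out_ids: list[str] = []
    out_rows: list[np.ndarray] = []
    for gid in sorted(groups, key=first_pos.get):
        rows = groups[gid]
        if len(rows) == 1 or (restrict_to is not None and gid not in restrict_to):
            for i in rows:
                out_ids.append(gid)
                out_rows.append(values[i])
            continue
        best: tuple[int, int] | None = None
        best_corr = -np.inf
        for i, j in combinations(rows, 2):
            c = _pearson(values[i], values[j])
            if c is not None and c > best_corr:
                best_corr, best = c, (i, j)
        if best is None:
            logger.warning(
                "%s: gene %s has only degenerate duplicate rows; dropped",
                step_name,
                gid,
            )
            continue
        if best_corr >= corr_threshold:
            out_ids.append(gid)
            out_rows.append((values[best[0]] + values[best[1]]) / 2.0)
        else:
            logger.info(
                "%s: gene %s duplicates uncorrelated (max %.3f); dropped",
                step_name,
                gid,
                best_corr,
            )
    return pd.DataFrame(
        np.array(out_rows).reshape(len(out_rows), matrix.shape[1]),
        index=pd.Index(out_ids, name=matrix.index.name or "gene"),
        columns=matrix.columns,
    )


def collapse_repeated_genes(
    matrix: pd.DataFrame,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """One gene, one row: merge or drop repeated measurements of a gene."""
    out = _collapse_duplicate_rows(matrix, corr_threshold, "collapse_repeated_genes")
    if report is not None:
        report.add("collapse_repeated_genes", len(out))
    return out


def collapse_homologene_duplicates(
    matrix: pd.DataFrame,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    flagged: frozenset[str] | None = None,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Collapse several symbols mapping to one homologene id."""
    out = _collapse_duplicate_rows(
        matrix, corr_threshold, "collapse_homologene_duplicates", restrict_to=None
    )
    if report is not None:
        report.add("collapse_homologene_duplicates", len(out))
    return out


def _harmonize_matrix(
    matrix: pd.DataFrame, species: str, ortholog_map: OrthologMap
) -> pd.DataFrame:
    """Re-key an averaged symbol matrix by homologene id (drop unmapped)."""
    keep_pos: list[int] = []
    new_ids: list[str] = []
    for i, symbol in enumerate(matrix.index):
        ids = ortholog_map.lookup(species, symbol)
        if len(ids) == 1:
            keep_pos.append(i)
            new_ids.append(next(iter(ids)))
    out = matrix.iloc[keep_pos].copy()
    out.index = pd.Index(new_ids, name="homologene_id")
    return out


def run_filter_pipeline(
    dataset: ExpressionDataset,
    ortholog_map: OrthologMap | None = None,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
) -> tuple[pd.DataFrame, FilterReport, ReplicateConsistencyStats]:
    """Full per-dataset filter chain, reported step by step.

    Order: multi-gene row removal -> replicate-consistency filter (yields
    the replicate-averaged matrix) -> repeated-gene collapse on symbols ->
    homologene harmonization -> homologene-duplicate collapse.  When no
    ortholog map is given, the last two steps are skipped and the matrix
    stays symbol-keyed.
    """
    report = FilterReport(dataset_id=dataset.dataset_id)
    report.add("initial", dataset.n_genes)
    ds = drop_multigene_rows(dataset, report=report)
    averaged, stats = replicate_consistency_filter(
        ds, sd_multiplier=sd_multiplier, report=report
    )
    averaged = collapse_repeated_genes(
        averaged, corr_threshold=corr_threshold, report=report
    )
    if ortholog_map is not None:
        averaged = _harmonize_matrix(averaged, dataset.species, ortholog_map)
        report.add("homologene_harmonization", len(set(averaged.index)))
        averaged = collapse_homologene_duplicates(
            averaged, corr_threshold=corr_threshold, report=report
        )
    return averaged, report, stats
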