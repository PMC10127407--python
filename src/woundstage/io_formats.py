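"""Expression-table and ortholog-map I/O, plus homologene harmonization.

Expression tables are plain UTF-8 TSV: first column ``gene`` holds gene
symbols (or homologene ids), remaining columns are samples named
``<time>h_r<replicate>``, e.g. ``72h_r2``.  Interval-sampled biopsies
(pooled time windows, as in human burn studies) use ``<start>-<end>h_r<k>``;
internally the interval midpoint is the working timepoint.  Times are hours;
day-denominated sources must be converted before writing (1 d = 24 h).
Intensities are strictly positive linear-scale values.

The ortholog map is a three-column TSV ``homologene_id  species  symbol``
and is queryable in both directions, which is what harmonizing mouse and
human symbols onto shared homologene ids requires.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    BaselineError,
    ConfigurationError,
    ParseError,
    PositivityError,
    SchemaError,
)

logger = logging.getLogger(__name__)

MULTIGENE_DELIMITER = "//"

_SAMPLE_RE = re.compile(
    r"^(?P<t0>\d+(?:\.\d+)?)(?:-(?P<t1>\d+(?:\.\d+)?))?h_r(?P<rep>\d+)$"
)


def _format_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else repr(float(t))


@dataclass
class ExpressionDataset:
    """Replicate-resolved gene x timepoint intensity tensor with metadata.

    ``intensities`` is indexed ``(gene, timepoint, replicate)``.  The first
    timepoint must be 0 h (the unwounded baseline) and at least three
    post-wounding timepoints must be present, mirroring the selection
    criteria for usable longitudinal wound datasets.
    """

    dataset_id: str
    species: str
    gene_ids: list[str]
    timepoints_h: np.ndarray
    intensities: np.ndarray
    time_intervals_h: list[tuple[float, float]] | None = None
    flagged_homologene: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.timepoints_h = np.asarray(self.timepoints_h, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise SchemaError("intensities must be a (gene, time, replicate) tensor")
        n_genes, n_time, _ = self.intensities.shape
        if len(self.gene_ids) != n_genes:
            raise SchemaError("gene_ids length does not match intensity tensor")
        if len(self.timepoints_h) != n_time:
            raise SchemaError("timepoints_h length does not match intensity tensor")
        if n_time < 4:
            raise SchemaError(
                "need a baseline plus at least three post-wounding timepoints"
            )
        if np.any(np.diff(self.timepoints_h) <= 0):
            raise SchemaError("timepoints_h must be strictly increasing")
        if self.timepoints_h[0] != 0.0:
            raise BaselineError(
                f"no baseline: first timepoint is {self.timepoints_h[0]} h, not 0 h"
            )
        if n_genes and not np.all(self.intensities > 0):
            g, t, r = np.argwhere(~(self.intensities > 0))[0]
            raise PositivityError(
                f"non-positive intensity for gene {self.gene_ids[g]!r} at "
                f"{self.timepoints_h[t]} h replicate {r + 1}"
            )
        if self.time_intervals_h is not None:
            if len(self.time_intervals_h) != n_time:
                raise SchemaError("time_intervals_h length mismatch")
            self.time_intervals_h = [
                (float(a), float(b)) for a, b in self.time_intervals_h
            ]

    @property
    def n_genes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[2]

    def replicate_mean(self):
        """Replicate-averaged matrix as a gene x timepoint DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            self.intensities.mean(axis=2),
            index=pd.Index(self.gene_ids, name="gene"),
            columns=self.timepoints_h,
        )

    def subset_genes(self, keep: np.ndarray) -> "ExpressionDataset":
        """Row subset by boolean mask or integer positions (order kept)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            gene_ids=[self.gene_ids[i] for i in keep],
            intensities=self.intensities[keep],
        )


@dataclass(frozen=True)
class OrthologRecord:
    homologene_id: str
    species: str
    symbol: str


class OrthologMap:
    """Bidirectional (species, symbol) <-> homologene-id lookup."""

    def __init__(self, records: list[OrthologRecord]):
        for rec in records:
            if not (rec.homologene_id and rec.species and rec.symbol):
                raise ParseError(f"ortholog record with empty field: {rec}")
        # deduplicate, preserving insertion order
        self.records = list(dict.fromkeys(records))
        self._by_symbol: dict[tuple[str, str], set[str]] = {}
        self._by_id: dict[str, dict[str, list[str]]] = {}
        for rec in self.records:
            self._by_symbol.setdefault((rec.species, rec.symbol), set()).add(
                rec.homologene_id
            )
            sym = self._by_id.setdefault(rec.homologene_id, {}).setdefault(
                rec.species, []
            )
            if rec.symbol not in sym:
                sym.append(rec.symbol)

    def lookup(self, species: str, symbol: str) -> set[str]:
        """Homologene ids for a (species, symbol) pair; empty set if unmapped."""
        return set(self._by_symbol.get((species, symbol), set()))

    def symbols(self, homologene_id: str, species: str) -> list[str]:
        return list(self._by_id.get(homologene_id, {}).get(species, []))

    @property
    def species(self) -> set[str]:
        return {rec.species for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FilterReport:
    """Ordered per-step surviving-gene counts for one dataset."""

    dataset_id: str
    steps: list[tuple[str, int]] = field(default_factory=list)

    def add(self, step_name: str, genes_remaining: int) -> None:
        if self.steps and genes_remaining > self.steps[-1][1]:
            raise ValueError(
                "genes_remaining must be non-increasing across filter steps"
            )
        self.steps.append((step_name, int(genes_remaining)))
        logger.info(
            "%s: %s -> %d genes", self.dataset_id, step_name, genes_remaining
        )

    def counts(self) -> dict[str, int]:
        return dict(self.steps)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("step\tgenes_remaining\n")
            for name, n in self.steps:
                fh.write(f"{name}\t{n}\n")


def read_expression_table(
    path,
    dataset_id: str | None = None,
    species: str = "unknown",
    gene_column: str = "gene",
) -> ExpressionDataset:
    """Parse a sample-annotated expression TSV into an ExpressionDataset.

    Raises :class:`SchemaError` on malformed headers or duplicate
    (time, replicate) columns, :class:`BaselineError` when no 0 h column
    exists and :class:`ParseError`/:class:`PositivityError` on bad cells.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != gene_column:
            raise SchemaError(
                f"first column must be {gene_column!r}, got {header[:1]}"
            )
        samples: list[tuple[float, tuple[float, float], int]] = []
        seen: set[tuple[float, int]] = set()
        for col in header[1:]:
            m = _SAMPLE_RE.match(col)
            if m is None:
                raise SchemaError(f"cannot parse sample column name {col!r}")
            t0 = float(m.group("t0"))
            t1 = float(m.group("t1")) if m.group("t1") else t0
            if t1 < t0:
                raise SchemaError(f"interval end before start in column {col!r}")
            mid = (t0 + t1) / 2.0
            rep = int(m.group("rep"))
            if (mid, rep) in seen:
                raise SchemaError(f"duplicate (time, replicate) column {col!r}")
            seen.add((mid, rep))
            samples.append((mid, (t0, t1), rep))
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            vals = []
            for col, raw in zip(header[1:], fields[1:]):
                try:
                    v = float(raw)
                except ValueError as exc:
                    raise ParseError(
                        f"gene {fields[0]!r}, column {col!r}: "
                        f"non-numeric intensity {raw!r}"
                    ) from exc
                if not v > 0:
                    raise ParseError(
                        f"gene {fields[0]!r}, column {col!r}: "
                        f"non-positive intensity {raw!r}"
                    )
                vals.append(v)
            rows.append(vals)

    times = sorted({mid for mid, _, _ in samples})
    reps = sorted({rep for _, _, rep in samples})
    if 0.0 not in times:
        raise BaselineError("no baseline: table has no 0 h sample column")
    pos = {
        (mid, rep): j for j, (mid, _, rep) in enumerate(samples)
    }
    missing = [
        (t, r) for t in times for r in reps if (t, r) not in pos
    ]
    if missing:
        raise SchemaError(f"incomplete (time, replicate) grid; missing {missing}")
    data = np.empty((len(gene_ids), len(times), len(reps)))
    for j, t in enumerate(times):
        for k, r in enumerate(reps):
            col = pos[(t, r)]
            for i in range(len(gene_ids)):
                data[i, j, k] = rows[i][col]
    intervals = None
    by_mid = {mid: iv for mid, iv, _ in samples}
    if any(a != b for a, b in by_mid.values()):
        intervals = [by_mid[t] for t in times]
    if dataset_id is None:
        import os

        dataset_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ExpressionDataset(
        dataset_id=dataset_id,
        species=species,
        gene_ids=gene_ids,
        timepoints_h=np.array(times),
        intensities=data,
        time_intervals_h=intervals,
    )


def write_expression_table(dataset: ExpressionDataset, path) -> None:
    """Serialize to TSV with full float precision (round-trip exact)."""
    cols = []
    for j, t in enumerate(dataset.timepoints_h):
        if dataset.time_intervals_h is not None:
            a, b = dataset.time_intervals_h[j]
            stem = (
                _format_time(a)
                if a == b
                else f"{_format_time(a)}-{_format_time(b)}"
            )
        else:
            stem = _format_time(t)
        for k in range(dataset.n_replicates):
            cols.append((f"{stem}h_r{k + 1}", j, k))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(name for name, _, _ in cols) + "\n")
        for i, gene in enumerate(dataset.gene_ids):
            vals = "\t".join(
                repr(float(dataset.intensities[i, j, k])) for _, j, k in cols
            )
            fh.write(f"{gene}\t{vals}\n")


def read_ortholog_map(path) -> OrthologMap:
    """Read a ``homologene_id  species  symbol`` TSV (header optional)."""
    records: list[OrthologRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and fields[:1] == ["homologene_id"]:
                continue
            if len(fields) != 3 or not all(f.strip() for f in fields):
                raise ParseError(f"line {lineno}: malformed ortholog row {line!r}")
            records.append(OrthologRecord(*[f.strip() for f in fields]))
    return OrthologMap(records)


def harmonize_to_homologene(
    dataset: ExpressionDataset,
    ortholog_map: OrthologMap,
    report: FilterReport | None = None,
) -> ExpressionDataset:
    """Re-key a symbol-indexed dataset by homologene id.

    Symbols with no mapping, or ambiguously mapping to several homologene
    ids, are dropped (conservative).  When one homologene id ends up
    covering several symbol rows of this dataset, all rows are retained
    and the id is flagged for later correlation-based collapse.
    """
    if dataset.species not in ortholog_map.species:
        raise ConfigurationError(
            f"species {dataset.species!r} absent from ortholog map"
        )
    keep: list[int] = []
    new_ids: list[str] = []
    n_dropped = 0
    for i, symbol in enumerate(dataset.gene_ids):
        ids = ortholog_map.lookup(dataset.species, symbol)
        if len(ids) == 1:
            keep.append(i)
            new_ids.append(next(iter(ids)))
        else:
            n_dropped += 1
            if len(ids) > 1:
                logger.warning(
                    "%s: symbol %s ambiguously maps to %d homologene ids; dropped",
                    dataset.dataset_id,
                    symbol,
                    len(ids),
                )
    counts: dict[str, int] = {}
    for hid in new_ids:
        counts[hid] = counts.get(hid, 0) + 1
    flagged = frozenset(hid for hid, c in counts.items() if c >= 2)
    out = replace(
        dataset.subset_genes(np.array(keep, dtype=int)),
        gene_ids=new_ids,
        flagged_homologene=flagged,
    )
    if report is not None:
        report.add("homologene_harmonization", out.n_genes)
    if n_dropped:
        logger.info(
            "%s: dropped %d symbols without unique homologene mapping",
            dataset.dataset_id,
            n_dropped,
        )
    return out
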