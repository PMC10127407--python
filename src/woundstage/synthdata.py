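"""Synthetic multi-dataset wound time-course cohorts with ground truth.

The generator emulates the statistical structure the pipeline assumes in
real microarray cohorts: a few datasets on heterogeneous time grids
(one dense reference grid, one sparse grid, one interval-sampled), three
replicates per sample, five cluster-structured temporal archetypes with
per-gene amplitude jitter, bounded multiplicative replicate noise on
linear intensities, occasional extreme outlier replicates, repeated gene
rows (both correlated copies and uncorrelated decoys), multi-gene probe
rows, cross-species symbols tied together by a homologene map, and
low-fold-change nuisance genes that exercise top-k signature selection.

Every planted feature is recorded in a :class:`CohortTruth` registry so
tests can compare pipeline output against ground truth.  Cohorts are
fully reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_formats import ExpressionDataset, OrthologMap, OrthologRecord
from .stager import StageLabel, assign_stage

N_CLUSTERS = 5


@dataclass
class DatasetGridSpec:
    """Time sampling of one synthetic dataset."""

    dataset_id: str
    species: str
    timepoints_h: tuple[float, ...]
    time_intervals_h: tuple[tuple[float, float], ...] | None = None
    n_replicates: int = 3


#: Default grids mirror common study designs: a dense 8-point reference
#: time course, a sparse 4-point course, and an interval-pooled course.
DEFAULT_GRIDS: tuple[DatasetGridSpec, ...] = (
    DatasetGridSpec(
        "synth_mouse_surgical", "mouse", (0, 6, 12, 24, 72, 120, 168, 240)
    ),
    DatasetGridSpec("synth_mouse_burn", "mouse", (0, 2, 72, 336)),
    DatasetGridSpec(
        "synth_human_burn",
        "human",
        (0, 48, 132, 264),
        time_intervals_h=((0, 0), (24, 72), (96, 168), (192, 336)),
    ),
)

SYMBOL_PREFIXES = {"mouse": "Wnd", "human": "WND"}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults define the study conditions."""

    grids: tuple[DatasetGridSpec, ...] = DEFAULT_GRIDS
    genes_per_cluster: int = 10
    n_nuisance: int = 20
    #: SD of the log-scale multiplicative replicate noise.  The log-noise
    #: is uniform (bounded), so the only extreme replicate events in a
    #: cohort are the registered planted outliers and the outlier
    #: registry is exhaustive ground truth for the consistency filter.
    noise_sigma: float = 0.05
    outlier_rate: float = 0.02  # per nuisance gene per dataset
    outlier_factor: float = 10.0
    outlier_targets: str = "nuisance"  # or "any"
    duplicate_row_rate: float = 0.1  # correlated copies of signature genes
    decoy_row_rate: float = 0.15  # uncorrelated extra rows on nuisance genes
    homologene_dup_rate: float = 0.1  # second human symbol per homologene id
    n_multigene_rows: int = 3
    baseline_intensity_range: tuple[float, float] = (100.0, 1000.0)
    amplitude_jitter: tuple[float, float] = (0.8, 1.2)
    peak_amplitude: float = 1.2
    width_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "outlier_rate",
            "duplicate_row_rate",
            "decoy_row_rate",
            "homologene_dup_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.genes_per_cluster < 1:
            raise ValidationError("genes_per_cluster must be >= 1")
        if self.outlier_targets not in {"nuisance", "any"}:
            raise ValidationError("outlier_targets must be 'nuisance' or 'any'")
        if len(self.grids) < 2:
            raise ValidationError("a cohort needs at least two datasets")

    @property
    def n_signature(self) -> int:
        return N_CLUSTERS * self.genes_per_cluster


@dataclass
class CohortTruth:
    """Registry of everything the generator planted."""

    signature_genes: list[str]  # homologene ids
    nuisance_genes: list[str]
    cluster_of: dict[str, int]  # homologene id -> 1..5
    stage_of: dict[tuple[str, float], StageLabel]
    symbol_of: dict[tuple[str, str], str]  # (species, homologene id) -> symbol
    outlier_rows: dict[str, set[str]] = field(default_factory=dict)  # ds -> symbols
    duplicate_rows: dict[str, set[str]] = field(default_factory=dict)
    decoy_rows: dict[str, set[str]] = field(default_factory=dict)
    homologene_dups: dict[str, set[str]] = field(default_factory=dict)
    multigene_rows: dict[str, set[str]] = field(default_factory=dict)


def _log_bump(
    t: np.ndarray, mu: float, width: float, width_down: float | None = None
) -> np.ndarray:
    """Unit bump in log-time, zero at t = 0; unique maximum at t = mu.

    ``width_down`` makes the bump asymmetric (fast rise, slow decay or
    vice versa), the typical shape of transcriptional responses.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    z = np.log(t[pos] / mu)
    w = np.where(z < 0, width, width_down if width_down is not None else width)
    out[pos] = np.exp(-((z / w) ** 2))
    return out


def generate_archetypes(spec: CohortSpec):
    """Five positive temporal profiles, one per cluster.

    Cluster 1 starts at its maximum and is downregulated (with a shallow
    late recovery); clusters 2-5 are bumps peaking near 24, 72, 120 and
    ~240 h.  On the dense reference grid each profile's maximum falls in
    its own peak-time bin.
    """
    a = spec.peak_amplitude
    w = spec.width_scale

    def c1(t):
        t = np.asarray(t, dtype=float)
        return (
            0.2
            + 0.8 * np.exp(-t / 24.0)
            + 0.3 * (1.0 - np.exp(-((t / 250.0) ** 2)))
        )

    def make_bump(mu, width, width_down=None, amp=1.0):
        def f(t):
            return 0.25 + amp * a * _log_bump(
                t, mu, width * w, width_down * w if width_down else None
            )

        return f

    # the 72 h-peaking inflammatory archetype rises fast and strongly
    # (chemokine-like), hence the wide rising flank and doubled amplitude
    return [
        c1,
        make_bump(24.0, 0.85),
        make_bump(72.0, 1.5, 0.8, amp=2.0),
        make_bump(120.0, 0.5),
        make_bump(240.0, 0.25, 0.6),
    ]


def _symbol(species: str, index: int) -> str:
    return f"{SYMBOL_PREFIXES[species]}{index:04d}"


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[ExpressionDataset], OrthologMap, CohortTruth]:
    """Generate expression datasets, an ortholog map and the truth registry."""
    rng = np.random.default_rng(spec.seed)
    archetypes = generate_archetypes(spec)
    n_sig, n_nui = spec.n_signature, spec.n_nuisance
    n_genes = n_sig + n_nui

    hg_ids = [f"HG{i:04d}" for i in range(n_genes)]
    signature_genes = hg_ids[:n_sig]
    nuisance_genes = hg_ids[n_sig:]
    cluster_of = {
        hg_ids[i]: i // spec.genes_per_cluster + 1 for i in range(n_sig)
    }

    records: list[OrthologRecord] = []
    symbol_of: dict[tuple[str, str], str] = {}
    for i, hid in enumerate(hg_ids):
        for sp in SYMBOL_PREFIXES:
            sym = _symbol(sp, i)
            records.append(OrthologRecord(hid, sp, sym))
            symbol_of[(sp, hid)] = sym

    truth = CohortTruth(
        signature_genes=signature_genes,
        nuisance_genes=nuisance_genes,
        cluster_of=cluster_of,
        stage_of={},
        symbol_of=symbol_of,
    )

    # fixed per-(dataset, gene) nuisance wiggle so nuisance rows are
    # reproducible profiles, not pure noise
    datasets: list[ExpressionDataset] = []
    for grid in spec.grids:
        times = np.asarray(grid.timepoints_h, dtype=float)
        ds_id = grid.dataset_id
        for jt, t in enumerate(times):
            key_time = (
                tuple(grid.time_intervals_h[jt])
                if grid.time_intervals_h is not None
                else t
            )
            truth.stage_of[(ds_id, float(t))] = assign_stage(key_time)
        truth.outlier_rows[ds_id] = set()
        truth.duplicate_rows[ds_id] = set()
        truth.decoy_rows[ds_id] = set()
        truth.homologene_dups[ds_id] = set()
        truth.multigene_rows[ds_id] = set()

        rows: list[tuple[str, np.ndarray]] = []  # (symbol, profile over times)

        def noisy(profile: np.ndarray) -> np.ndarray:
            """(time, replicate) matrix with bounded multiplicative noise.

            Log-noise is uniform with SD ``noise_sigma`` (support
            +/- sqrt(3) sigma), keeping intensities positive.
            """
            half = np.sqrt(3.0) * spec.noise_sigma
            z = rng.uniform(-half, half, size=(len(times), grid.n_replicates))
            return profile[:, None] * np.exp(z)

        profiles: dict[str, np.ndarray] = {}
        for i in range(n_sig):
            sym = _symbol(grid.species, i)
            c = cluster_of[hg_ids[i]]
            u = rng.uniform(*spec.amplitude_jitter)
            scale = rng.uniform(*spec.baseline_intensity_range)
            base = archetypes[c - 1](times)
            # jitter the dynamic part, keep the resting level
            profile = scale * (base[0] + u * (base - base[0]))
            profile = np.maximum(profile, 1e-6)
            profiles[sym] = profile
            rows.append((sym, profile))
            if rng.uniform() < spec.duplicate_row_rate:
                rows.append((sym, profile))
                truth.duplicate_rows[ds_id].add(sym)
            if grid.species == "human" and rng.uniform() < spec.homologene_dup_rate:
                sym_b = _symbol(grid.species, i) + "B"
                records.append(OrthologRecord(hg_ids[i], "human", sym_b))
                rows.append((sym_b, profile))
                truth.homologene_dups[ds_id].add(sym_b)
        for i in range(n_sig, n_genes):
            sym = _symbol(grid.species, i)
            scale = rng.uniform(*spec.baseline_intensity_range)
            wiggle = 1.0 + rng.uniform(-0.02, 0.02, size=len(times))
            profile = scale * wiggle
            profiles[sym] = profile
            rows.append((sym, profile))
            if rng.uniform() < spec.decoy_row_rate:
                # a second row with shuffled dynamics: uncorrelated with
                # the first in expectation, same low dynamic range
                rows.append((sym, rng.permutation(profile)))
                truth.decoy_rows[ds_id].add(sym)
        for j in range(spec.n_multigene_rows):
            p = SYMBOL_PREFIXES[grid.species]
            sym = f"{p}Ax{j:03d}//{p}Bx{j:03d}"
            mu = float(rng.choice([24.0, 72.0, 120.0]))
            scale = rng.uniform(*spec.baseline_intensity_range)
            rows.append((sym, scale * (0.25 + _log_bump(times, mu, 0.7))))
            truth.multigene_rows[ds_id].add(sym)

        order = rng.permutation(len(rows))
        gene_ids = [rows[i][0] for i in order]
        tensor = np.stack([noisy(rows[i][1]) for i in order])

        # plant extreme single-replicate outliers
        candidates = (
            [g for g in gene_ids if g in profiles and g not in
             {_symbol(grid.species, i) for i in range(n_sig)}]
            if spec.outlier_targets == "nuisance"
            else [g for g in gene_ids if "//" not in g]
        )
        seen: set[str] = set()
        for pos, g in enumerate(gene_ids):
            if g not in candidates or g in seen:
                continue
            seen.add(g)
            if rng.uniform() < spec.outlier_rate:
                jt = int(rng.integers(0, len(times)))
                k = int(rng.integers(0, grid.n_replicates))
                tensor[pos, jt, k] *= spec.outlier_factor
                truth.outlier_rows[ds_id].add(g)

        datasets.append(
            ExpressionDataset(
                dataset_id=ds_id,
                species=grid.species,
                gene_ids=gene_ids,
                timepoints_h=times,
                intensities=tensor,
                time_intervals_h=(
                    list(grid.time_intervals_h)
                    if grid.time_intervals_h is not None
                    else None
                ),
            )
        )

    return datasets, OrthologMap(records), truth
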