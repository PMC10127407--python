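import numpy as np
import pandas as pd
import pytest

from woundstage.errors import (
    BaselineError,
    ClusterUnrepresentedError,
    MembershipError,
    PositivityError,
    WoundStageError,
)
from woundstage.signature import (
    DEFAULT_CLUSTER_BINS_H,
    BiopsyPoint,
    GeneSignature,
    assign_clusters,
    cluster_for_time,
    embed_biopsies,
    embeddings_to_frame,
    max_fold_change,
    select_signature,
)

from conftest import TIMES8, make_dataset


def matrix(rows, ids, times=TIMES8):
    return pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=pd.Index(ids, name="gene"),
        columns=list(times),
    )


class TestMaxFoldChange:
    def test_formula(self):
        assert max_fold_change([2.0, 6.0, 4.0]) == pytest.approx(2.0)

    def test_constant_series_is_zero(self):
        assert max_fold_change([5.0, 5.0, 5.0]) == 0.0

    def test_requires_two_points(self):
        with pytest.raises(WoundStageError):
            max_fold_change([1.0])

    def test_requires_positive(self):
        with pytest.raises(PositivityError):
            max_fold_change([1.0, 0.0, 2.0])


class TestClusterForTime:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (0.0, 1),
            (6.0, 1),
            (12.0, 1),
            (18.0, 1),
            (24.0, 2),
            (48.0, 2),
            (72.0, 3),
            (96.0, 3),
            (120.0, 4),
            (132.0, 4),
            (168.0, 5),
            (240.0, 5),
            (10000.0, 5),
        ],
    )
    def test_reference_grid_binning(self, t, expected):
        assert cluster_for_time(t) == expected

    def test_uncovered_time(self):
        with pytest.raises(WoundStageError, match="not covered"):
            cluster_for_time(30.0, bins=((0, 10), (20, 25)))


class TestSelectSignature:
    def test_intersection_of_top_k(self):
        d1 = matrix(
            [
                [1, 10, 1, 1, 1, 1, 1, 1],  # fold change 9
                [1, 5, 1, 1, 1, 1, 1, 1],  # 4
                [1, 2, 1, 1, 1, 1, 1, 1],  # 1
            ],
            ["A", "B", "C"],
        )
        d2 = matrix(
            [
                [1, 1, 8, 1, 1, 1, 1, 1],  # 7
                [1, 1, 1, 1, 1, 1, 1, 1.5],  # 0.5
                [1, 6, 1, 1, 1, 1, 1, 1],  # 5
            ],
            ["A", "B", "C"],
        )
        assert select_signature({"d1": d1, "d2": d2}, top_k=2) == ["A"]

    def test_tie_break_lexicographic(self):
        d = matrix([[1, 3, 1, 1, 1, 1, 1, 1]] * 3, ["Z", "A", "M"])
        # all tied; top-2 must be the lexicographically first two
        sel = select_signature({"d1": d, "d2": d}, top_k=2)
        assert sel == ["A", "M"]

    def test_needs_two_datasets(self):
        d = matrix([[1, 2, 1, 1, 1, 1, 1, 1]], ["A"])
        with pytest.raises(WoundStageError, match="at least two"):
            select_signature({"d1": d})

    def test_duplicate_index_rejected(self):
        d = matrix([[1, 2, 1, 1, 1, 1, 1, 1]] * 2, ["A", "A"])
        with pytest.raises(WoundStageError, match="unique"):
            select_signature({"d1": d, "d2": d}, top_k=1)

    def test_dataset_order_invariance(self):
        rng = np.random.default_rng(0)
        d1 = matrix(rng.uniform(1, 10, size=(20, 8)), [f"G{i}" for i in range(20)])
        d2 = matrix(rng.uniform(1, 10, size=(20, 8)), [f"G{i}" for i in range(20)])
        assert select_signature({"a": d1, "b": d2}, top_k=10) == select_signature(
            {"b": d2, "a": d1}, top_k=10
        )


class TestAssignClusters:
    def test_peak_binning(self):
        rows = np.ones((3, 8))
        rows[0, 1] = 5.0  # peak at 6 h -> cluster 1
        rows[1, 4] = 5.0  # peak at 72 h -> cluster 3
        rows[2, 7] = 5.0  # peak at 240 h -> cluster 5
        sig = assign_clusters(matrix(rows, ["A", "B", "C"]), ["A", "B", "C"])
        assert [sig.cluster_of[g] for g in ["A", "B", "C"]] == [1, 3, 5]
        assert sig.peak_time_h["B"] == 72.0

    def test_tied_maximum_uses_earliest(self):
        rows = np.ones((1, 8))
        rows[0, 2] = rows[0, 5] = 5.0  # 12 h and 120 h tie -> 12 h, cluster 1
        sig = assign_clusters(matrix(rows, ["A"]), ["A"])
        assert sig.cluster_of["A"] == 1

    def test_missing_gene(self):
        with pytest.raises(MembershipError, match="absent"):
            assign_clusters(matrix(np.ones((1, 8)), ["A"]), ["A", "Nope"])

    def test_signature_validates_peak_in_bin(self):
        with pytest.raises(WoundStageError, match="outside its cluster bin"):
            GeneSignature(
                genes=["A"],
                cluster_of={"A": 2},
                peak_time_h={"A": 100.0},
                reference_dataset_id="d",
            )

    def test_tsv_round_trip(self, tmp_path):
        rows = np.ones((2, 8))
        rows[0, 3] = 2.0
        rows[1, 6] = 2.0
        sig = assign_clusters(
            matrix(rows, ["A", "B"]), ["A", "B"], reference_dataset_id="ref"
        )
        path = tmp_path / "sig.tsv"
        sig.to_tsv(path)
        back = GeneSignature.from_tsv(path, reference_dataset_id="ref")
        assert back.genes == sig.genes
        assert back.cluster_of == sig.cluster_of
        assert back.peak_time_h == sig.peak_time_h


def five_cluster_signature():
    return GeneSignature(
        genes=[f"S{c}" for c in range(1, 6)],
        cluster_of={f"S{c}": c for c in range(1, 6)},
        peak_time_h={"S1": 0.0, "S2": 24.0, "S3": 72.0, "S4": 120.0, "S5": 240.0},
        reference_dataset_id="ref",
    )


class TestEmbedBiopsies:
    def _dataset(self, n_rep=2, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.uniform(10, 100, size=(5, 8, n_rep))
        return make_dataset(
            values, gene_ids=[f"S{c}" for c in range(1, 6)], timepoints=TIMES8
        )

    def test_baseline_embeds_to_ones(self):
        pts = embed_biopsies(self._dataset(), five_cluster_signature())
        for p in pts:
            if p.time_h == 0.0:
                assert np.allclose(p.embedding, 1.0)

    def test_cluster_mean_and_normalization(self):
        sig = GeneSignature(
            genes=["A", "B", "C", "D", "E", "F"],
            cluster_of={"A": 1, "B": 1, "C": 2, "D": 3, "E": 4, "F": 5},
            peak_time_h={"A": 0, "B": 6, "C": 24, "D": 72, "E": 120, "F": 240},
            reference_dataset_id="ref",
        )
        values = np.ones((6, 8, 1))
        values[0, 1, 0] = 4.0  # A at 6 h
        values[1, 1, 0] = 2.0  # B at 6 h
        values[:, 0, 0] = [2.0, 4.0, 1.0, 1.0, 1.0, 1.0]  # baselines
        ds = make_dataset(values, gene_ids=list("ABCDEF"), timepoints=TIMES8)
        pts = embed_biopsies(ds, sig)
        p6 = next(p for p in pts if p.time_h == 6.0)
        # J_1(6h) = (4+2)/2 = 3; J_1(0) = (2+4)/2 = 3 -> coordinate 1.0
        assert p6.embedding[0] == pytest.approx(1.0)
        assert p6.genes_per_cluster == (2, 1, 1, 1, 1)

    def test_per_replicate_vs_dataset_mean_baseline(self):
        ds = self._dataset(n_rep=3, seed=1)
        per_rep = embed_biopsies(ds, five_cluster_signature())
        ds_mean = embed_biopsies(
            ds, five_cluster_signature(), baseline_policy="dataset_mean"
        )
        j0 = ds.intensities[:, 0, :]
        k = 1  # replicate 2
        expected_ratio = j0[:, k] / j0.mean(axis=1)
        p_rep = next(p for p in per_rep if p.time_h == 6.0 and p.replicate == k + 1)
        p_ds = next(p for p in ds_mean if p.time_h == 6.0 and p.replicate == k + 1)
        assert np.allclose(p_ds.embedding / p_rep.embedding, expected_ratio)

    def test_unknown_policy(self):
        with pytest.raises(WoundStageError, match="baseline policy"):
            embed_biopsies(self._dataset(), five_cluster_signature(), "median")

    def test_missing_genes_silently_excluded(self):
        sig = five_cluster_signature()
        sig.genes.append("S6")
        sig.cluster_of["S6"] = 1
        sig.peak_time_h["S6"] = 6.0
        pts = embed_biopsies(self._dataset(), sig)
        assert pts[0].genes_per_cluster == (1, 1, 1, 1, 1)

    def test_unrepresented_cluster_raises(self):
        values = np.random.default_rng(2).uniform(1, 2, size=(4, 8, 1))
        ds = make_dataset(
            values, gene_ids=["S1", "S2", "S3", "S4"], timepoints=TIMES8
        )
        with pytest.raises(ClusterUnrepresentedError, match="cluster 5"):
            embed_biopsies(ds, five_cluster_signature())

    def test_duplicate_rows_averaged_before_cluster_mean(self):
        values = np.ones((6, 8, 1))
        values[0, 1, 0] = 2.0
        values[5, 1, 0] = 4.0  # second S1 row
        ds = make_dataset(
            values,
            gene_ids=["S1", "S2", "S3", "S4", "S5", "S1"],
            timepoints=TIMES8,
        )
        pts = embed_biopsies(ds, five_cluster_signature())
        p6 = next(p for p in pts if p.time_h == 6.0)
        assert p6.embedding[0] == pytest.approx(3.0)  # mean of the two rows

    def test_no_baseline_timepoint(self):
        ds = self._dataset()
        ds.timepoints_h = ds.timepoints_h.copy()
        ds.timepoints_h[0] = 1.0
        with pytest.raises(BaselineError):
            embed_biopsies(ds, five_cluster_signature())

    def test_interval_metadata_propagates(self):
        values = np.random.default_rng(3).uniform(1, 2, size=(5, 4, 1))
        ds = make_dataset(
            values,
            gene_ids=[f"S{c}" for c in range(1, 6)],
            timepoints=[0, 48, 132, 264],
            time_intervals=[(0, 0), (24, 72), (96, 168), (192, 336)],
        )
        pts = embed_biopsies(ds, five_cluster_signature())
        assert next(p for p in pts if p.time_h == 48.0).time_interval_h == (24, 72)


class TestBiopsyPoint:
    def test_embedding_shape_enforced(self):
        with pytest.raises(WoundStageError, match="5-vector"):
            BiopsyPoint("d", 1, 0.0, np.ones(4))

    def test_embedding_positivity(self):
        with pytest.raises(PositivityError):
            BiopsyPoint("d", 1, 0.0, np.array([1, 1, 0, 1, 1.0]))

    def test_frame_columns(self):
        p = BiopsyPoint("d", 2, 6.0, np.arange(1.0, 6.0))
        df = embeddings_to_frame([p])
        assert list(df.columns) == [
            "dataset",
            "time_h",
            "replicate",
            "C1",
            "C2",
            "C3",
            "C4",
            "C5",
            "assigned_stage",
        ]
        assert df.loc[0, "C3"] == 3.0


class TestDefaultBins:
    def test_bins_partition_positive_axis(self):
        edges = [b for bin_ in DEFAULT_CLUSTER_BINS_H for b in bin_]
        assert edges[0] == 0.0 and edges[-1] == float("inf")
        for i in range(1, len(DEFAULT_CLUSTER_BINS_H)):
            assert DEFAULT_CLUSTER_BINS_H[i - 1][1] == DEFAULT_CLUSTER_BINS_H[i][0]
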