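import numpy as np
import pytest

from woundstage.errors import DomainError, WoundStageError
from woundstage.signature import BiopsyPoint
from woundstage.stager import (
    STEP_SUBSPACES,
    BinarySvm,
    StageLabel,
    StageModel,
    SvmHyperParams,
    assign_stage,
    evaluate_predictions,
    label_points,
    predict_stage,
    predict_stages,
    train_stager,
)


def point(time_h, embedding, dataset="d", replicate=1, interval=None):
    return BiopsyPoint(
        dataset_id=dataset,
        replicate=replicate,
        time_h=time_h,
        embedding=np.asarray(embedding, dtype=float),
        time_interval_h=interval,
    )


def labeled_training_points():
    """A small, cleanly separable cloud with all four stages."""
    raw = [
        (0.0, [1.0, 1.0, 1.0, 1.0, 1.0]),
        (6.0, [0.9, 1.2, 1.4, 1.0, 1.0]),
        (24.0, [0.6, 3.0, 6.0, 1.0, 1.0]),
        (48.0, [0.5, 2.0, 8.0, 1.2, 1.0]),
        (72.0, [0.4, 1.5, 9.0, 3.0, 1.0]),
        (120.0, [0.5, 1.2, 6.0, 6.0, 1.0]),
        (168.0, [0.6, 1.1, 4.0, 4.0, 1.6]),
        (240.0, [0.8, 1.0, 2.0, 1.7, 5.0]),
        (336.0, [0.9, 1.0, 1.3, 1.1, 4.5]),
    ]
    return label_points([point(t, e) for t, e in raw])


class TestAssignStage:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (0.0, StageLabel.HEMOSTASIS),
            (11.9, StageLabel.HEMOSTASIS),
            (12.0, StageLabel.INFLAMMATION),
            (48.0, StageLabel.INFLAMMATION),
            (48.1, StageLabel.PROLIFERATION),
            (168.0, StageLabel.PROLIFERATION),
            (168.1, StageLabel.REMODELING),
            (1000.0, StageLabel.REMODELING),
        ],
    )
    def test_time_rule(self, t, expected):
        assert assign_stage(t) is expected

    def test_interval_uses_midpoint(self):
        assert assign_stage((24.0, 72.0)) is StageLabel.INFLAMMATION  # mid 48
        assert assign_stage((96.0, 168.0)) is StageLabel.PROLIFERATION

    def test_negative_time(self):
        with pytest.raises(DomainError):
            assign_stage(-1.0)

    def test_bad_interval(self):
        with pytest.raises(DomainError):
            assign_stage((72.0, 24.0))


class TestLabelPoints:
    def test_interval_precedence_and_overrides(self):
        pts = [
            point(48.0, np.ones(5), interval=(96.0, 168.0)),
            point(24.0, np.ones(5)),
        ]
        label_points(pts)
        assert pts[0].assigned_stage is StageLabel.PROLIFERATION  # via interval
        assert pts[1].assigned_stage is StageLabel.INFLAMMATION
        label_points(pts, overrides={("d", 24.0): StageLabel.HEMOSTASIS})
        assert pts[1].assigned_stage is StageLabel.HEMOSTASIS

    def test_str_of_labels(self):
        assert str(StageLabel.REMODELING) == "remodeling"


class TestBinarySvm:
    def test_manual_poly_decision_matches_sklearn(self):
        from sklearn.svm import SVC

        rng = np.random.default_rng(0)
        X = rng.uniform(0, 5, size=(30, 5))
        y = ["a" if x[0] + x[4] > 5 else "b" for x in X]
        hyper = SvmHyperParams()
        clf = SVC(kernel="poly", C=1.0, degree=3, gamma=1.0, coef0=1.0)
        clf.fit(X[:, [0, 4]], y)
        svm = BinarySvm(
            kernel="poly",
            subspace=(0, 4),
            classes=tuple(clf.classes_),
            support_vectors=clf.support_vectors_,
            dual_coef=clf.dual_coef_[0],
            intercept=float(clf.intercept_[0]),
            degree=hyper.degree,
            gamma=hyper.gamma,
            coef0=hyper.coef0,
        )
        assert np.allclose(
            svm.decision_function(X), clf.decision_function(X[:, [0, 4]])
        )
        assert svm.predict(X) == list(clf.predict(X[:, [0, 4]]))

    def test_dict_round_trip(self):
        pts = labeled_training_points()
        model = train_stager(pts)
        for step in (model.step1, model.step2, model.step3):
            back = BinarySvm.from_dict(step.to_dict())
            X = np.stack([p.embedding for p in pts])
            assert np.allclose(
                back.decision_function(X), step.decision_function(X)
            )

    def test_unsupported_kernel(self):
        svm = BinarySvm(
            kernel="rbf",
            subspace=(0, 1),
            classes=("a", "b"),
            support_vectors=np.ones((1, 2)),
            dual_coef=np.ones(1),
        )
        with pytest.raises(WoundStageError, match="unsupported kernel"):
            svm.decision_function(np.ones((1, 5)))


class TestTrainAndPredict:
    def test_cascade_recovers_training_labels(self):
        pts = labeled_training_points()
        model = train_stager(pts)
        preds = predict_stages(model, pts)
        assert [p.assigned_stage for p in pts] == preds

    def test_step_subspaces(self):
        pts = labeled_training_points()
        model = train_stager(pts)
        assert model.step1.subspace == STEP_SUBSPACES["step1"] == (2, 3, 4)
        assert model.step2.subspace == (0, 4)
        assert model.step3.subspace == (1, 4)
        assert model.step1.kernel == "linear"
        assert model.step2.kernel == model.step3.kernel == "poly"

    def test_training_is_deterministic(self):
        pts = labeled_training_points()
        m1, m2 = train_stager(pts), train_stager(pts)
        X = np.stack([p.embedding for p in pts])
        for s1, s2 in [(m1.step1, m2.step1), (m1.step2, m2.step2), (m1.step3, m2.step3)]:
            assert np.array_equal(s1.decision_function(X), s2.decision_function(X))

    def test_unlabeled_points_rejected(self):
        with pytest.raises(WoundStageError, match="assigned stage"):
            train_stager([point(0.0, np.ones(5))])

    def test_single_class_step_warns_and_is_constant(self):
        pts = label_points([point(24.0, [1, 1, 2, 1, 1.0]), point(240.0, np.ones(5))])
        pts2 = label_points(
            [point(24.0, [1, 1, 3, 1, 1.0]), point(336.0, [1, 1, 1, 1, 4.0])]
        )
        with pytest.warns(UserWarning, match="single class"):
            model = train_stager(pts + pts2)
        # step2 saw only remodeling points -> constant classifier
        assert model.step2.kernel == "constant"

    def test_empty_step3_raises(self):
        pts = label_points([point(0.0, np.ones(5)), point(24.0, [1, 1, 3, 1, 1.0])])
        with pytest.raises(WoundStageError, match="step3"), pytest.warns(UserWarning):
            train_stager(pts)

    def test_predict_single_point(self):
        pts = labeled_training_points()
        model = train_stager(pts)
        assert predict_stage(model, pts[0]) is StageLabel.HEMOSTASIS

    def test_non_finite_embedding_rejected(self):
        pts = labeled_training_points()
        model = train_stager(pts)
        bad = point(6.0, np.ones(5))
        bad.embedding = np.array([1.0, np.nan, 1.0, 1.0, 1.0])
        with pytest.raises(WoundStageError, match="finite"):
            predict_stages(model, [bad])

    def test_provenance(self):
        pts = labeled_training_points()
        model = train_stager(pts, seed=7)
        assert model.provenance["n_training_points"] == len(pts)
        assert model.provenance["seed"] == 7
        assert model.provenance["datasets"] == ["d"]

    def test_json_round_trip(self, tmp_path):
        pts = labeled_training_points()
        model = train_stager(pts, hyper=SvmHyperParams(degree=2))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = StageModel.from_json(path)
        assert back.hyper == model.hyper
        assert predict_stages(back, pts) == predict_stages(model, pts)

    def test_standardize_option(self):
        pts = labeled_training_points()
        model = train_stager(pts, hyper=SvmHyperParams(standardize=True))
        assert model.step1.feature_mean is not None
        preds = predict_stages(model, pts)
        assert preds[0] is StageLabel.HEMOSTASIS


class TestEvaluation:
    def test_counts_per_sampling_time(self):
        pts = labeled_training_points()
        model = train_stager(pts)
        extra = label_points(
            [point(24.0, [0.6, 3.0, 6.1, 1.0, 1.0], replicate=2)]
        )
        result = evaluate_predictions(model, pts + extra)
        assert result.n_total == len(pts) + 1
        row = result.table[result.table.time_h == 24.0].iloc[0]
        assert row["n_total"] == 2
        assert row["inflammation"] == 2
        assert result.accuracy == pytest.approx(1.0)

    def test_errors_counted(self):
        pts = labeled_training_points()
        model = train_stager(pts)
        wrong = label_points([point(240.0, [1, 1, 1, 1, 1.0], replicate=2)])
        result = evaluate_predictions(model, wrong)
        assert result.n_errors == 1
        assert result.accuracy == 0.0

    def test_unlabeled_rejected(self):
        pts = labeled_training_points()
        model = train_stager(pts)
        with pytest.raises(WoundStageError):
            evaluate_predictions(model, [point(6.0, np.ones(5))])
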