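"""Reference stage labels and the 3-step cascaded SVM classifier.

Reference labels follow the canonical timing of acute wound repair:
hemostasis before 12 h, inflammation from 12 h through 48 h (the window
of peak inflammatory-gene upregulation), proliferation from day 3
through day 7, remodeling afterwards.  Interval-sampled biopsies are
labeled by their interval midpoint, and per-dataset override tables can
replace the time rule where a study's annotation disagrees with it.

Classification works in the 5-D embedding of normalized mean cluster
values (coordinates C1..C5) through three binary maximum-margin steps:

* step 1 — linear SVM on {C3, C4, C5}: inflammation vs the rest;
* step 2 — polynomial SVM on {C1, C5}: hemostasis vs
  proliferation/remodeling;
* step 3 — polynomial SVM on {C2, C5}: proliferation vs remodeling.

Polynomial kernels default to degree 3 with offset 1, unit box
constraint and no feature standardization (the embeddings are already
ratio-normalized); all of this is configurable.  Fitting is delegated to
scikit-learn, but fitted machines are reduced to their support vectors,
dual coefficients and intercept so a model round-trips through JSON and
prediction is a pure function of the stored parameters.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import DomainError, WoundStageError
from .signature import BiopsyPoint

logger = logging.getLogger(__name__)


class StageLabel(str, Enum):
    HEMOSTASIS = "hemostasis"
    INFLAMMATION = "inflammation"
    PROLIFERATION = "proliferation"
    REMODELING = "remodeling"

    def __str__(self) -> str:  # noqa: D105
        return self.value


#: Stage boundaries in hours: inflammation is [12, 48], proliferation
#: (48, 168] (days 3-7, day 7 inclusive), remodeling beyond day 7.
HEMOSTASIS_END_H = 12.0
INFLAMMATION_END_H = 48.0
PROLIFERATION_END_H = 168.0


def assign_stage(time) -> StageLabel:
    """Reference stage for a point time in hours or an (start, end) interval."""
    if isinstance(time, (tuple, list)):
        start, end = float(time[0]), float(time[1])
        if start < 0 or end < start:
            raise DomainError(f"invalid time interval {time}")
        t = (start + end) / 2.0
    else:
        t = float(time)
    if t < 0:
        raise DomainError(f"negative time {t} h")
    if t < HEMOSTASIS_END_H:
        return StageLabel.HEMOSTASIS
    if t <= INFLAMMATION_END_H:
        return StageLabel.INFLAMMATION
    if t <= PROLIFERATION_END_H:
        return StageLabel.PROLIFERATION
    return StageLabel.REMODELING


def label_points(
    points: list[BiopsyPoint],
    overrides: dict[tuple[str, float], StageLabel] | None = None,
) -> list[BiopsyPoint]:
    """Attach reference stage labels in place (and return the list).

    ``overrides`` maps ``(dataset_id, time_h)`` to an explicit label and
    takes precedence over the time rule, accommodating studies whose own
    stage annotation departs from the canonical timing.
    """
    for p in points:
        key = (p.dataset_id, p.time_h)
        if overrides and key in overrides:
            p.assigned_stage = StageLabel(overrides[key])
        elif p.time_interval_h is not None:
            p.assigned_stage = assign_stage(p.time_interval_h)
        else:
            p.assigned_stage = assign_stage(p.time_h)
    return points


@dataclass
class SvmHyperParams:
    """Kernel settings shared by the two polynomial cascade steps."""

    degree: int = 3
    coef0: float = 1.0
    gamma: float = 1.0
    box_constraint: float = 1.0
    standardize: bool = False


@dataclass
class BinarySvm:
    """A fitted binary SVM reduced to pure prediction parameters.

    ``classes`` is sorted; a positive decision value selects
    ``classes[1]`` (the scikit-learn convention).  ``kernel`` may also be
    ``"constant"`` for degenerate single-class training sets.
    """

    kernel: str
    subspace: tuple[int, ...]
    classes: tuple[str, ...]
    support_vectors: np.ndarray | None = None
    dual_coef: np.ndarray | None = None
    intercept: float = 0.0
    degree: int = 3
    gamma: float = 1.0
    coef0: float = 1.0
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.subspace]
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_scale
        if self.kernel == "constant":
            return np.full(len(X), -1.0 if len(self.classes) == 1 else 0.0)
        gram = X @ self.support_vectors.T
        if self.kernel == "poly":
            gram = (self.gamma * gram + self.coef0) ** self.degree
        elif self.kernel != "linear":
            raise WoundStageError(f"unsupported kernel {self.kernel!r}")
        return gram @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> list[str]:
        if self.kernel == "constant":
            return [self.classes[0]] * len(np.atleast_2d(X))
        dec = self.decision_function(X)
        return [self.classes[1] if d > 0 else self.classes[0] for d in dec]

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("support_vectors", "dual_coef", "feature_mean", "feature_scale"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        d["subspace"] = list(self.subspace)
        d["classes"] = list(self.classes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BinarySvm":
        kw = dict(d)
        kw["subspace"] = tuple(kw["subspace"])
        kw["classes"] = tuple(kw["classes"])
        for key in ("support_vectors", "dual_coef", "feature_mean", "feature_scale"):
            if kw.get(key) is not None:
                kw[key] = np.asarray(kw[key], dtype=float)
        return cls(**kw)


STEP_SUBSPACES = {
    "step1": (2, 3, 4),  # {C3, C4, C5}
    "step2": (0, 4),  # {C1, C5}
    "step3": (1, 4),  # {C2, C5}
}


def _fit_binary(
    X: np.ndarray,
    y: list[str],
    subspace: tuple[int, ...],
    kernel: str,
    hyper: SvmHyperParams,
    step: str,
) -> BinarySvm:
    classes = tuple(sorted(set(y)))
    if len(classes) == 1:
        warnings.warn(
            f"{step}: single class {classes[0]!r} in training data; "
            "fitting a constant classifier",
            stacklevel=2,
        )
        return BinarySvm(kernel="constant", subspace=subspace, classes=classes)
    Xs = X[:, subspace]
    mean = scale = None
    if hyper.standardize:
        mean = Xs.mean(axis=0)
        scale = Xs.std(axis=0)
        scale[scale == 0] = 1.0
        Xs = (Xs - mean) / scale
    clf = SVC(
        kernel=kernel,
        C=hyper.box_constraint,
        degree=hyper.degree,
        gamma=hyper.gamma,
        coef0=hyper.coef0,
    )
    clf.fit(Xs, y)
    return BinarySvm(
        kernel=kernel,
        subspace=subspace,
        classes=tuple(clf.classes_),
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        degree=hyper.degree,
        gamma=hyper.gamma,
        coef0=hyper.coef0,
        feature_mean=mean,
        feature_scale=scale,
    )


@dataclass
class StageModel:
    """The three cascade SVMs plus training provenance."""

    step1: BinarySvm
    step2: BinarySvm
    step3: BinarySvm
    hyper: SvmHyperParams = field(default_factory=SvmHyperParams)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "step1": self.step1.to_dict(),
            "step2": self.step2.to_dict(),
            "step3": self.step3.to_dict(),
            "hyper": asdict(self.hyper),
            "provenance": self.provenance,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StageModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            step1=BinarySvm.from_dict(payload["step1"]),
            step2=BinarySvm.from_dict(payload["step2"]),
            step3=BinarySvm.from_dict(payload["step3"]),
            hyper=SvmHyperParams(**payload["hyper"]),
            provenance=payload.get("provenance", {}),
        )


REST = "rest"


def train_stager(
    points: list[BiopsyPoint],
    hyper: SvmHyperParams | None = None,
    seed: int = 0,
) -> StageModel:
    """Fit the three-step cascade on labeled embedded biopsies.

    Step 1 sees all points (inflammation vs rest); step 2 the
    non-inflammation points (hemostasis vs rest); step 3 only
    proliferation and remodeling points.  Training is deterministic given
    the points, hyperparameters and seed.
    """
    hyper = hyper or SvmHyperParams()
    if any(p.assigned_stage is None for p in points):
        raise WoundStageError("all training points need an assigned stage")
    X = np.stack([p.embedding for p in points])
    y = [StageLabel(p.assigned_stage).value for p in points]

    y1 = [
        StageLabel.INFLAMMATION.value if s == StageLabel.INFLAMMATION.value else REST
        for s in y
    ]
    step1 = _fit_binary(X, y1, STEP_SUBSPACES["step1"], "linear", hyper, "step1")

    mask2 = [s != StageLabel.INFLAMMATION.value for s in y]
    X2 = X[mask2]
    y2 = [
        StageLabel.HEMOSTASIS.value if s == StageLabel.HEMOSTASIS.value else REST
        for s, m in zip(y, mask2)
        if m
    ]
    if len(y2) == 0:
        step2 = BinarySvm(
            kernel="constant",
            subspace=STEP_SUBSPACES["step2"],
            classes=(StageLabel.HEMOSTASIS.value,),
        )
        warnings.warn("step2: no non-inflammation training points", stacklevel=2)
    else:
        step2 = _fit_binary(X2, y2, STEP_SUBSPACES["step2"], "poly", hyper, "step2")

    mask3 = [
        s in (StageLabel.PROLIFERATION.value, StageLabel.REMODELING.value) for s in y
    ]
    X3 = X[mask3]
    y3 = [s for s, m in zip(y, mask3) if m]
    if len(y3) == 0:
        raise WoundStageError(
            "step3 training set empty: no proliferation or remodeling points"
        )
    step3 = _fit_binary(X3, y3, STEP_SUBSPACES["step3"], "poly", hyper, "step3")

    provenance = {
        "datasets": sorted({p.dataset_id for p in points}),
        "replicates": sorted({p.replicate for p in points}),
        "n_training_points": len(points),
        "seed": int(seed),
    }
    return StageModel(step1=step1, step2=step2, step3=step3, hyper=hyper,
                      provenance=provenance)


def predict_stage(model: StageModel, point: BiopsyPoint) -> StageLabel:
    """Cascade prediction for a single embedded biopsy."""
    return predict_stages(model, [point])[0]


def predict_stages(model: StageModel, points: list[BiopsyPoint]) -> list[StageLabel]:
    X = np.stack([p.embedding for p in points])
    if X.shape[1] != 5 or not np.all(np.isfinite(X)):
        raise WoundStageError("embeddings must be finite 5-vectors")
    out: list[StageLabel | None] = [None] * len(points)
    p1 = model.step1.predict(X)
    rest_idx = [i for i, lab in enumerate(p1) if lab != StageLabel.INFLAMMATION.value]
    for i, lab in enumerate(p1):
        if lab == StageLabel.INFLAMMATION.value:
            out[i] = StageLabel.INFLAMMATION
    if rest_idx:
        p2 = model.step2.predict(X[rest_idx])
        late_idx = []
        for i, lab in zip(rest_idx, p2):
            if lab == StageLabel.HEMOSTASIS.value:
                out[i] = StageLabel.HEMOSTASIS
            else:
                late_idx.append(i)
        if late_idx:
            p3 = model.step3.predict(X[late_idx])
            for i, lab in zip(late_idx, p3):
                out[i] = StageLabel(lab)
    return out  # type: ignore[return-value]


@dataclass
class EvaluationResult:
    """Per sampling-time predicted-stage counts plus overall accuracy."""

    table: pd.DataFrame
    n_total: int
    n_errors: int

    @property
    def accuracy(self) -> float:
        return 1.0 - self.n_errors / self.n_total if self.n_total else float("nan")


def evaluate_predictions(
    model: StageModel, points: list[BiopsyPoint]
) -> EvaluationResult:
    """Count predicted stages per (dataset, sampling time) against labels."""
    if any(p.assigned_stage is None for p in points):
        raise WoundStageError("all evaluation points need an assigned stage")
    preds = predict_stages(model, points)
    rows: dict[tuple[str, float], dict] = {}
    for p, pred in zip(points, preds):
        key = (p.dataset_id, p.time_h)
        row = rows.setdefault(
            key,
            {
                "dataset": p.dataset_id,
                "time_h": p.time_h,
                "assigned_stage": StageLabel(p.assigned_stage).value,
                **{s.value: 0 for s in StageLabel},
                "n_total": 0,
                "n_errors": 0,
            },
        )
        row[pred.value] += 1
        row["n_total"] += 1
        if pred != StageLabel(p.assigned_stage):
            row["n_errors"] += 1
    table = pd.DataFrame(
        sorted(rows.values(), key=lambda r: (r["dataset"], r["time_h"]))
    )
    return EvaluationResult(
        table=table,
        n_total=int(table["n_total"].sum()),
        n_errors=int(table["n_errors"].sum()),
    )
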