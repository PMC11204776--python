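"""Two-stage classification of laxity grade, raw-signal baseline, evaluation.

Stage 1 assigns a speed class from the four pivot-segment features; stage 2
holds one model per class that assigns the laxity grade within that class.
A test case routed to a class that had no training data is reported as
"unclassifiable" rather than forced into a guess, and the classifiability
ratio is reported alongside the metrics.

Metrics are micro-averaged, so accuracy == recall == precision on complete
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .model import FEATURE_COLUMNS

__all__ = [
    "UNCLASSIFIABLE",
    "METHODS",
    "SplitSpec",
    "EvalReport",
    "make_model",
    "split_train_test",
    "train_baseline_raw",
    "TwoStageClassifier",
    "evaluate",
    "recording_dataset",
]

UNCLASSIFIABLE = "unclassifiable"
METHODS = ("lr", "svm", "dt", "rf")


def make_model(method: str, seed: int = 0):
    """Fixed-hyperparameter classifier for one of lr/svm/dt/rf."""
    method = method.lower()
    if method == "lr":
        return make_pipeline(
            StandardScaler(), LogisticRegression(C=1.0, max_iter=5000)
        )
    if method == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    if method == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if method == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


@dataclass(frozen=True)
class SplitSpec:
    """Per-grade held-out test draw."""

    per_grade_test_count: int = 3
    min_grade_count_for_test: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_grade_test_count < 0 or self.min_grade_count_for_test < 0:
            raise ValueError("counts must be >= 0")


def split_train_test(
    dataset: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a per-grade test group; grades below the threshold stay in train.

    For every grade with at least ``min_grade_count_for_test`` cases,
    exactly ``per_grade_test_count`` cases are drawn (seeded, without
    replacement) into the test partition.  The split is disjoint and
    exhaustive.
    """
    if dataset.empty:
        raise ValueError("empty dataset")
    if "grade" not in dataset.columns:
        raise ValueError("dataset must carry a 'grade' column")
    rng = np.random.default_rng(spec.seed)
    test_idx: list = []
    for grade in sorted(dataset["grade"].unique()):
        members = dataset.index[dataset["grade"] == grade].to_numpy()
        if len(members) >= spec.min_grade_count_for_test:
            take = min(spec.per_grade_test_count, len(members))
            test_idx.extend(rng.choice(members, size=take, replace=False).tolist())
    mask = dataset.index.isin(test_idx)
    test = dataset.loc[mask]
    train = dataset.loc[~mask]
    return train, test


def train_baseline_raw(
    signals: Sequence[np.ndarray],
    labels: Sequence,
    method: str = "svm",
    seed: int = 0,
    resample_to: Optional[int] = None,
):
    """Fit a classifier directly on raw X-axis sample vectors.

    Mixed-length signals are rejected unless ``resample_to`` is given, in
    which case every signal is linearly resampled to that length.
    """
    arrays = [np.asarray(s, dtype=float) for s in signals]
    lengths = {len(a) for a in arrays}
    if len(lengths) > 1 and resample_to is None:
        raise ValueError(
            f"signals have mixed lengths {sorted(lengths)}; pass resample_to"
        )
    if resample_to is not None:
        arrays = [
            np.interp(
                np.linspace(0, 1, resample_to), np.linspace(0, 1, len(a)), a
            )
            for a in arrays
        ]
    X = np.vstack(arrays)
    model = make_model(method, seed)
    model.fit(X, np.asarray(labels))
    return model


def _feature_matrix(data: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        return data[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    return arr


@dataclass
class TwoStageClassifier:
    """Class-then-grade classifier over the four pivot features."""

    stage1_method: str = "svm"
    stage2_method: str = "dt"
    seed: int = 0
    stage1_model: object = None
    stage2_models: dict[int, object] = field(default_factory=dict)
    schema_version: str = "1"

    def fit(
        self,
        features: Union[pd.DataFrame, np.ndarray],
        klass: Optional[Sequence[int]] = None,
        grade: Optional[Sequence[int]] = None,
    ) -> "TwoStageClassifier":
        if isinstance(features, pd.DataFrame):
            if klass is None:
                klass = features["klass"].to_numpy()
            if grade is None:
                grade = features["grade"].to_numpy()
        if klass is None or grade is None:
            raise ValueError("klass and grade labels are required")
        X = _feature_matrix(features)
        klass = np.asarray(klass, dtype=int)
        grade = np.asarray(grade, dtype=float)  # NaN marks an ungraded case
        self.stage1_model = make_model(self.stage1_method, self.seed)
        self.stage1_model.fit(X, klass)
        self.stage2_models = {}
        for c in sorted(set(klass.tolist())):
            mask = (klass == c) & ~np.isnan(grade)
            sub_y = grade[mask].astype(int)
            if len(sub_y) == 0:
                continue  # class without graded training data -> unclassifiable
            if len(set(sub_y.tolist())) == 1:
                # degenerate one-grade class: remember the constant
                self.stage2_models[c] = ("const", int(sub_y[0]))
            else:
                model = make_model(self.stage2_method, self.seed)
                model.fit(X[mask], sub_y)
                self.stage2_models[c] = ("model", model)
        return self

    def predict_class(self, features) -> np.ndarray:
        if self.stage1_model is None:
            raise ValueError("classifier is not fitted")
        return np.asarray(self.stage1_model.predict(_feature_matrix(features)))

    def predict(self, features) -> np.ndarray:
        """Predict grades; cases routed to untrained classes come back
        as :data:`UNCLASSIFIABLE`."""
        X = _feature_matrix(features)
        classes = self.predict_class(X)
        out = np.empty(len(X), dtype=object)
        for i, (row, c) in enumerate(zip(X, classes)):
            entry = self.stage2_models.get(int(c))
            if entry is None:
                out[i] = UNCLASSIFIABLE
            elif entry[0] == "const":
                out[i] = entry[1]
            else:
                out[i] = int(entry[1].predict(row.reshape(1, -1))[0])
        return out


@dataclass
class EvalReport:
    """Micro-averaged metrics plus the confusion matrix they derive from."""

    accuracy: float  # percent
    recall: float  # percent
    precision: float  # percent
    f1: float  # in [0, 1]
    confusion_matrix: np.ndarray  # rows = truth, columns = predicted
    labels: list
    n_test: int
    n_total: int
    classifiability_ratio: float  # in [0, 1]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "labels": list(self.labels),
            "n_test": self.n_test,
            "n_total": self.n_total,
            "classifiability_ratio": self.classifiability_ratio,
        }


def evaluate(predictions: Sequence, truth: Sequence) -> EvalReport:
    """Score predictions against truth; unclassifiable cases are excluded
    from the confusion matrix and reported via the classifiability ratio."""
    preds = list(predictions)
    true = list(truth)
    if len(preds) != len(true):
        raise ValueError(
            f"length mismatch: {len(preds)} predictions vs {len(true)} truths"
        )
    if len(preds) == 0:
        raise ValueError("nothing to evaluate")
    def _plain(v):
        return int(v) if isinstance(v, np.integer) else v

    pairs = [
        (_plain(p), _plain(t))
        for p, t in zip(preds, true)
        if not (isinstance(p, str) and p == UNCLASSIFIABLE)
    ]
    ratio = len(pairs) / len(preds)
    if not pairs:
        raise ValueError("all predictions are unclassifiable")
    labels = sorted({t for _, t in pairs} | {p for p, _ in pairs})
    index = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for p, t in pairs:
        cm[index[t], index[p]] += 1
    correct = int(np.trace(cm))
    total = int(cm.sum())
    acc = 100.0 * correct / total
    return EvalReport(
        accuracy=acc,
        recall=acc,  # micro-averaged multi-class: all equal
        precision=acc,
        f1=acc / 100.0,
        confusion_matrix=cm,
        labels=labels,
        n_test=total,
        n_total=len(preds),
        classifiability_ratio=ratio,
    )


def recording_dataset(
    feature_table: pd.DataFrame, aggregate: str = "mean"
) -> pd.DataFrame:
    """Collapse a per-(recording, maneuver) feature table to one row per
    recording.

    ``aggregate='mean'`` (default) averages the features over the
    recording's maneuvers, which damps per-maneuver noise;
    ``aggregate='max-peak'`` keeps the single maneuver with the largest
    peak amplitude (the maneuver whose speed defines the class).
    """
    if feature_table.empty:
        raise ValueError("empty feature table")
    keys = ["subject_id", "evaluator_id", "repeat_index"]
    if aggregate == "max-peak":
        idx = feature_table.groupby(keys)["peak_amp"].idxmax()
        return feature_table.loc[idx].sort_values(keys, ignore_index=True)
    if aggregate != "mean":
        raise ValueError(f"aggregate must be 'mean' or 'max-peak', got {aggregate!r}")
    spec: dict = {c: "mean" for c in FEATURE_COLUMNS}
    spec["peak_amp"] = "max"
    for col in ("klass", "grade"):
        if col in feature_table.columns:
            spec[col] = "first"
    out = feature_table.groupby(keys, as_index=False).agg(spec)
    return out.sort_values(keys, ignore_index=True)
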