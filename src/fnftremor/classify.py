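"""Cross-validated classification of FNF feature vectors.

Four classical classifier families — linear discriminant analysis,
logistic regression, an RBF support vector machine and k-nearest
neighbours — evaluated by stratified k-fold cross-validation on three
tasks: healthy vs. tremor (ET and CD pooled), ET vs. CD, and the full
three-class problem. Features are standardized inside each fold using
training-fold statistics only, so no test information leaks into the
scaler.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "TASKS",
    "CLASSIFIERS",
    "LabeledDataset",
    "CVReport",
    "make_task",
    "make_classifier",
    "cross_validate",
]

TASKS = ("healthy_vs_tremor", "et_vs_cd", "three_class")
CLASSIFIERS = ("lda", "logistic", "svm", "knn")


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix (one row per recording) with class labels."""

    X: np.ndarray
    labels: np.ndarray
    ids: np.ndarray = None  # type: ignore[assignment]
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        labels = np.asarray(self.labels)
        if X.ndim != 2 or len(X) != len(labels):
            raise ValueError("X must be 2-D with one label per row")
        if not np.isfinite(X).all():
            raise ValueError("feature matrix contains missing/non-finite values")
        ids = (
            np.arange(len(X)) if self.ids is None else np.asarray(self.ids)
        )
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.X)

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass(frozen=True)
class CVReport:
    """Everything needed to reproduce one cross-validation run."""

    task: str
    classifier: str
    k: int
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float  # pooled correct / total
    seed: int
    confusion: dict  # {true_label: {predicted_label: count}}
    hyperparams: dict = field(default_factory=dict)
    n_samples: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "task": self.task,
            "classifier": self.classifier,
            "k": self.k,
            "fold_accuracies": list(self.fold_accuracies),
            "mean_accuracy": self.mean_accuracy,
            "seed": self.seed,
            "confusion": self.confusion,
            "hyperparams": self.hyperparams,
            "n_samples": self.n_samples,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def make_task(dataset: LabeledDataset, task: str) -> LabeledDataset:
    """Restrict/relabel a three-class dataset for one classification task.

    ``healthy_vs_tremor`` pools ET and CD into a single "tremor" class;
    ``et_vs_cd`` drops healthy recordings; ``three_class`` is the identity.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    labels = dataset.labels.astype(object)
    if task == "healthy_vs_tremor":
        needed = {"healthy"}
        labels = np.where(np.isin(labels, ["et", "cd"]), "tremor", labels)
        keep = np.ones(len(labels), dtype=bool)
        classes = {"healthy", "tremor"}
    elif task == "et_vs_cd":
        needed = {"et", "cd"}
        keep = np.isin(labels, ["et", "cd"])
        classes = needed
    else:
        needed = {"healthy", "et", "cd"}
        keep = np.ones(len(labels), dtype=bool)
        classes = needed
    out = LabeledDataset(
        X=dataset.X[keep],
        labels=labels[keep].astype(str),
        ids=dataset.ids[keep],
        feature_names=dataset.feature_names,
    )
    present = set(np.unique(out.labels).tolist())
    missing = classes - present
    if missing:
        raise ValueError(f"task {task!r} has empty class(es): {sorted(missing)}")
    return out


def make_classifier(
    name: str,
    standardize: bool = True,
    svm_c: float = 1.0,
    svm_gamma="scale",
    knn_k: int = 3,
    seed: int = 0,
):
    """Build a (optionally standardizing) sklearn pipeline by family name."""
    if name == "lda":
        clf = LinearDiscriminantAnalysis()
    elif name == "logistic":
        clf = LogisticRegression(max_iter=2000)
    elif name == "svm":
        clf = SVC(C=svm_c, gamma=svm_gamma, kernel="rbf", decision_function_shape="ovr")
    elif name == "knn":
        clf = KNeighborsClassifier(n_neighbors=knn_k)
    else:
        raise ValueError(f"classifier must be one of {CLASSIFIERS}")
    steps = ([("scale", StandardScaler())] if standardize else []) + [("clf", clf)]
    return Pipeline(steps)


def cross_validate(
    dataset: LabeledDataset,
    classifier: str = "svm",
    k: int = 5,
    seed: int = 0,
    task: str = "three_class",
    standardize: bool = True,
    svm_c: float = 1.0,
    knn_k: int = 3,
) -> CVReport:
    """Stratified k-fold cross-validation of one classifier family.

    The scaler and classifier are fitted on training folds only; accuracy
    is pooled (total correct over total). Deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(dataset.labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs at least two classes")
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        warnings.warn(
            f"smallest class ({counts.min()}) < k={k}; "
            "falling back to unstratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)

    X, y = dataset.X, dataset.labels.astype(str)
    fold_acc: list[float] = []
    confusion = {c: {c2: 0 for c2 in classes.astype(str)} for c in classes.astype(str)}
    n_correct = 0
    for train_idx, test_idx in splitter.split(X, y):
        model = make_classifier(
            classifier, standardize=standardize, svm_c=svm_c, knn_k=knn_k, seed=seed
        )
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        correct = int(np.sum(pred == y[test_idx]))
        n_correct += correct
        fold_acc.append(correct / len(test_idx))
        for t, p in zip(y[test_idx], pred):
            confusion[t][p] += 1

    return CVReport(
        task=task,
        classifier=classifier,
        k=k,
        fold_accuracies=tuple(fold_acc),
        mean_accuracy=n_correct / len(y),
        seed=seed,
        confusion=confusion,
        hyperparams={
            "standardize": standardize,
            "svm_c": svm_c,
            "svm_kernel": "rbf",
            "svm_gamma": "scale",
            "knn_k": knn_k,
            "multiclass": "one-vs-rest",
        },
        n_samples=len(y),
    )
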