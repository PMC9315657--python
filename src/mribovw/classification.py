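"""SVM training, prediction from the dual representation, and evaluation.

The support-vector machine separates classes with the kernel hyperplane

    y(x) = sum_a beta_a * K(x, x_a) + b1

over support vectors x_a.  Multiclass problems use a one-vs-one
decomposition; prediction evaluates every pairwise hyperplane directly
from the stored dual representation (support vectors, dual coefficients
beta, biases b1) and takes a majority vote, ties broken by the lowest
class index.  Features are standardized with train-set mean/sd inside
the model.

A small registry exposes the other classical classifiers used for
comparison runs (k-NN, decision tree, naive Bayes, random-forest
ensemble, MLP) behind one train/predict contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.metrics.pairwise import (
    linear_kernel,
    polynomial_kernel,
    rbf_kernel,
)
from sklearn.svm import SVC

from .errors import (
    DimensionError,
    EvaluationError,
    RegistryError,
    TrainingError,
)

MODEL_FORMAT_VERSION = 1


def _kernel_matrix(kind: str, params: dict, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    if kind == "linear":
        return linear_kernel(X, Y)
    if kind == "rbf":
        return rbf_kernel(X, Y, gamma=params["gamma"])
    if kind == "poly":
        return polynomial_kernel(
            X, Y, degree=params["degree"], gamma=params["gamma"], coef0=params["coef0"]
        )
    raise TrainingError(f"unsupported kernel {kind!r}")


@dataclass
class TrainedModel:
    """Dual representation of a one-vs-one multiclass SVM.

    Carries everything needed to evaluate the pairwise hyperplanes
    y(x) = sum beta_a K(x, x_a) + b1 without the fitting library:
    support vectors, dual coefficients, biases, kernel id/parameters,
    standardization statistics and the ordered label codebook.
    """

    support_vectors: np.ndarray      # (n_sv, d), standardized space
    dual_coefs: np.ndarray           # (n_classes - 1, n_sv), sklearn ovo layout
    biases: np.ndarray               # (n_pairs,)
    n_support: np.ndarray            # (n_classes,) SV count per class
    kernel: str
    kernel_params: dict
    label_codebook: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    C: float = 1.0

    @property
    def n_classes(self) -> int:
        return len(self.label_codebook)

    @property
    def class_pairs(self) -> list[tuple[int, int]]:
        return [
            (i, j)
            for i in range(self.n_classes)
            for j in range(i + 1, self.n_classes)
        ]

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        """Pairwise hyperplane values y(x), one column per (i, j) pair.

        Recomputed from the stored dual fields alone: for pair (i, j)
        the sum runs over the support vectors of classes i and j with
        their dual coefficients beta, plus the pair's bias b1.  Positive
        values vote for class j, negative for class i.
        """
        X = np.asarray(features, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.support_vectors.shape[1]:
            raise DimensionError(
                f"feature length {X.shape[1]} != model dimensionality "
                f"{self.support_vectors.shape[1]}"
            )
        Xs = self._standardize(X)
        K = _kernel_matrix(self.kernel, self.kernel_params, Xs, self.support_vectors)
        starts = np.concatenate([[0], np.cumsum(self.n_support)])
        sv_slices = [slice(starts[c], starts[c + 1]) for c in range(self.n_classes)]
        out = np.empty((Xs.shape[0], len(self.class_pairs)))
        for p, (i, j) in enumerate(self.class_pairs):
            beta_i = self.dual_coefs[j - 1, sv_slices[i]]
            beta_j = self.dual_coefs[i, sv_slices[j]]
            out[:, p] = (
                K[:, sv_slices[i]] @ beta_i
                + K[:, sv_slices[j]] @ beta_j
                + self.biases[p]
            )
        return out

    def save(self, path: str | Path) -> None:
        joblib.dump({"version": MODEL_FORMAT_VERSION, "model": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("version") != MODEL_FORMAT_VERSION:
            raise TrainingError(f"unsupported model archive version {blob.get('version')}")
        return blob["model"]


def train_svm(
    features: np.ndarray,
    labels: list[str] | np.ndarray,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
    gamma: float | str = "scale",
    degree: int = 3,
    coef0: float = 0.0,
) -> TrainedModel:
    """Fit the one-vs-one multiclass SVM on standardized features."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise TrainingError("features must be a 2-D array (n_samples, n_features)")
    if not np.all(np.isfinite(X)):
        raise TrainingError("features contain NaN or infinite values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise TrainingError("training requires at least 2 classes")
    if counts.min() < 2:
        lab = classes[counts.argmin()]
        raise TrainingError(f"class {lab!r} has fewer than 2 samples")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = (X - mean) / scale

    if gamma == "scale":
        var = Xs.var()
        gamma_val = 1.0 / (Xs.shape[1] * var) if var > 0 else 1.0
    else:
        gamma_val = float(gamma)

    clf = SVC(
        kernel=kernel,
        C=C,
        gamma=gamma_val,
        degree=degree,
        coef0=coef0,
        decision_function_shape="ovo",
        random_state=seed,
    ).fit(Xs, y)
    return TrainedModel(
        support_vectors=clf.support_vectors_,
        dual_coefs=clf.dual_coef_,
        biases=clf.intercept_,
        n_support=clf.n_support_,
        kernel=kernel,
        kernel_params={"gamma": gamma_val, "degree": degree, "coef0": coef0},
        label_codebook=tuple(str(c) for c in clf.classes_),
        scaler_mean=mean,
        scaler_scale=scale,
        C=C,
    )


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Majority vote over the pairwise hyperplanes; ties to lowest index."""
    dec = model.decision_values(features)
    votes = np.zeros((dec.shape[0], model.n_classes), dtype=np.int64)
    binary = model.n_classes == 2
    for p, (i, j) in enumerate(model.class_pairs):
        # the two-class decision function is oriented positive -> second
        # class; pairwise multiclass decisions are oriented the other
        # way.  An exact zero resolves to the lower class index.
        if binary:
            winners = np.where(dec[:, p] > 0, j, i)
        else:
            winners = np.where(dec[:, p] >= 0, i, j)
        np.add.at(votes, (np.arange(dec.shape[0]), winners), 1)
    # argmax takes the first maximum -> lowest class index on ties
    idx = votes.argmax(axis=1)
    codebook = np.asarray(model.label_codebook)
    return codebook[idx]


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix (rows true, cols predicted), accuracy, per-class TPR."""

    confusion: np.ndarray
    accuracy: float
    per_class_tpr: np.ndarray
    classes: tuple[str, ...]

    def summary(self) -> str:
        lines = [f"accuracy: {self.accuracy:.4f}"]
        for c, tpr in zip(self.classes, self.per_class_tpr):
            lines.append(f"TPR[{c}]: {tpr:.4f}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        header = "\t".join(("true\\pred",) + self.classes)
        rows = [header]
        for c, row in zip(self.classes, self.confusion):
            rows.append("\t".join([c] + [str(int(v)) for v in row]))
        rows.append("")
        rows.append(self.summary())
        Path(path).write_text("\n".join(rows) + "\n")


def evaluate(
    model: TrainedModel | object,
    test_features: np.ndarray,
    test_labels: list[str] | np.ndarray,
) -> EvaluationReport:
    """Confusion matrix, accuracy = trace/total, TPR_c = diag_c / row-sum_c."""
    y_true = np.asarray(test_labels)
    if y_true.size == 0:
        raise EvaluationError("empty test set")
    if isinstance(model, TrainedModel):
        codebook = model.label_codebook
        y_pred = predict(model, test_features)
    else:  # registry classifier with sklearn-style API
        codebook = tuple(str(c) for c in model.classes_)
        y_pred = model.predict(np.asarray(test_features, dtype=np.float64))
    unknown = set(map(str, y_true)) - set(codebook)
    if unknown:
        raise EvaluationError(f"labels {sorted(unknown)} not in codebook {codebook}")
    conf = confusion_matrix(y_true, y_pred, labels=list(codebook))
    total = conf.sum()
    accuracy = float(np.trace(conf)) / total
    row_sums = conf.sum(axis=1)
    tpr = np.divide(
        np.diag(conf), row_sums,
        out=np.zeros(len(codebook)), where=row_sums > 0,
    )
    return EvaluationReport(
        confusion=conf, accuracy=accuracy, per_class_tpr=tpr, classes=tuple(codebook)
    )


class _SklearnAdapter:
    """Standardize + fit wrapper giving registry classifiers one contract."""

    def __init__(self, estimator):
        self.estimator = estimator
        self.mean_ = None
        self.scale_ = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        self.estimator.fit((X - self.mean_) / self.scale_, np.asarray(y))
        return self

    @property
    def classes_(self):
        return self.estimator.classes_

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        return self.estimator.predict((X - self.mean_) / self.scale_)


def classifier_registry(name: str, seed: int = 0, **params):
    """Return a trainable classifier by name.

    ``svm`` returns a callable ``fit(X, y) -> TrainedModel`` wrapper;
    other names return standardizing sklearn adapters with
    ``fit``/``predict``.
    """
    names = ("svm", "knn", "tree", "naive_bayes", "ensemble", "nn")
    if name == "svm":
        class _SvmTrainer:
            classes_ = None

            def fit(self, X, y):
                self.model = train_svm(X, y, seed=seed, **params)
                self.classes_ = np.asarray(self.model.label_codebook)
                return self

            def predict(self, X):
                return predict(self.model, X)

        return _SvmTrainer()
    if name == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return _SklearnAdapter(KNeighborsClassifier(**({"n_neighbors": 5} | params)))
    if name == "tree":
        from sklearn.tree import DecisionTreeClassifier

        return _SklearnAdapter(DecisionTreeClassifier(random_state=seed, **params))
    if name == "naive_bayes":
        from sklearn.naive_bayes import GaussianNB

        return _SklearnAdapter(GaussianNB(**params))
    if name == "ensemble":
        from sklearn.ensemble import RandomForestClassifier

        return _SklearnAdapter(
            RandomForestClassifier(random_state=seed, **({"n_estimators": 100} | params))
        )
    if name == "nn":
        from sklearn.neural_network import MLPClassifier

        return _SklearnAdapter(
            MLPClassifier(random_state=seed, **({"max_iter": 500} | params))
        )
    raise RegistryError(f"unknown classifier {name!r}; options: {', '.join(names)}")
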