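"""Two-class linear discriminant analysis and its figures of merit.

The classifier is classical Fisher/LDA with pooled within-class covariance
and equal priors: weight vector ``S_p^-1 (mu_pos - mu_neg)``, bias placing
the boundary at the midpoint of the class means.  With equal priors this is
exactly the Mahalanobis-closest-class rule, which the tests exploit as an
independent oracle.

Training performance is summarized by leave-one-out cross-validation and the
held-out test set by a single fit on all training rows; both produce a
confusion table and the percentage figures of merit

    SEN = TP / (TP + FN) * 100
    SPE = TN / (TN + FP) * 100
    ACC = (TP + TN) / (TP + FN + TN + FP) * 100

where the "positive" class is, by convention, the first class label in
sorted order unless overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "DiscriminantModel",
    "ConfusionCounts",
    "FiguresOfMerit",
    "SingularCovarianceError",
    "UndefinedMetricError",
    "fit_lda",
    "score",
    "predict",
    "loo_cv",
    "figures_of_merit",
    "evaluate_split",
]

_COND_THRESHOLD = 1e10
_LAMBDA_START = 1e-8
_LAMBDA_CAP = 1e-2


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled covariance stayed singular after the regularization cap."""


class UndefinedMetricError(ZeroDivisionError):
    """A figure of merit has a zero denominator (no samples of one class)."""


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def to_dict(self) -> dict:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN}


@dataclass
class FiguresOfMerit:
    sensitivity: float
    specificity: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }

    def minimum(self) -> float:
        return min(self.sensitivity, self.specificity, self.accuracy)


@dataclass
class DiscriminantModel:
    """Fitted two-class LDA on a column subset."""

    weight_vector: np.ndarray
    bias: float
    class_means: dict
    pooled_covariance: np.ndarray
    selected_indices: list[int]
    positive_class: str
    negative_class: str
    regularization: float = 0.0


def _split_classes(X: np.ndarray, y: np.ndarray, positive_class: str | None):
    labels = sorted(set(y.tolist()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 classes, found {labels}")
    pos = positive_class if positive_class is not None else labels[0]
    if pos not in labels:
        raise ValueError(f"positive class {pos!r} not among {labels}")
    neg = labels[1] if pos == labels[0] else labels[0]
    return X[y == pos], X[y == neg], pos, neg


def fit_lda(
    X: np.ndarray,
    y,
    indices=None,
    positive_class: str | None = None,
) -> DiscriminantModel:
    """Fit pooled-covariance LDA on the given rows, restricted to ``indices``.

    Pooled covariance = within-class scatter / (n - 2).  If its condition
    number exceeds 1e10, a ridge ``lambda * trace/k * I`` is added with
    ``lambda`` escalated from 1e-8; the value used is recorded on the model
    (0.0 means the classical, unregularized fit).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray([str(c) for c in y])
    if indices is None:
        indices = list(range(X.shape[1]))
    indices = [int(i) for i in indices]
    Xs = X[:, indices]
    Xp, Xn, pos, neg = _split_classes(Xs, y, positive_class)
    if len(Xp) < 2 or len(Xn) < 2:
        raise ValueError("need at least 2 samples per class")
    k = Xs.shape[1]
    n = Xs.shape[0]
    mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
    scatter = (Xp - mu_p).T @ (Xp - mu_p) + (Xn - mu_n).T @ (Xn - mu_n)
    S = scatter / (n - 2)

    lam = 0.0
    S_reg = S
    if np.linalg.cond(S) > _COND_THRESHOLD:
        lam = _LAMBDA_START
        ridge = np.trace(S) / k if np.trace(S) > 0 else 1.0
        while lam <= _LAMBDA_CAP:
            S_reg = S + lam * ridge * np.eye(k)
            if np.linalg.cond(S_reg) <= _COND_THRESHOLD:
                break
            lam *= 10.0
        else:
            raise SingularCovarianceError(
                f"pooled covariance singular after regularization cap {_LAMBDA_CAP}"
            )
    w = np.linalg.solve(S_reg, mu_p - mu_n)
    bias = -float(w @ (mu_p + mu_n) / 2.0)
    return DiscriminantModel(
        weight_vector=w,
        bias=bias,
        class_means={pos: mu_p, neg: mu_n},
        pooled_covariance=S_reg,
        selected_indices=indices,
        positive_class=pos,
        negative_class=neg,
        regularization=lam,
    )


def score(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Discriminant value ``w . x + b`` per row (rows already restricted to
    the model's selected columns)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.weight_vector):
        raise ValueError(
            f"expected {len(model.weight_vector)} columns, got {X.shape[1]}"
        )
    return X @ model.weight_vector + model.bias


def predict(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Class labels per row; a score of exactly 0 goes to the negative class."""
    s = score(model, X)
    return np.where(s > 0, model.positive_class, model.negative_class)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, positive: str) -> ConfusionCounts:
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    return ConfusionCounts(
        TP=int(np.sum(t & p)),
        TN=int(np.sum(~t & ~p)),
        FP=int(np.sum(~t & p)),
        FN=int(np.sum(t & ~p)),
    )


def loo_cv(
    X: np.ndarray,
    y,
    indices=None,
    positive_class: str | None = None,
) -> tuple[ConfusionCounts, FiguresOfMerit]:
    """Leave-one-out cross-validation of the LDA on the training partition.

    Each row is predicted by a model fitted on the remaining rows.  A fold
    whose covariance cannot be stabilized is counted as a misclassification
    (with a warning), so the confusion table always totals ``n``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray([str(c) for c in y])
    labels = sorted(set(y.tolist()))
    pos = positive_class if positive_class is not None else labels[0]
    n = X.shape[0]
    preds = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            model = fit_lda(X[mask], y[mask], indices, positive_class=pos)
            cols = model.selected_indices
            preds[i] = predict(model, X[i : i + 1, cols])[0]
        except (SingularCovarianceError, ValueError):
            warnings.warn(f"LOO fold {i}: singular fit counted as misclassification")
            preds[i] = labels[1] if y[i] == labels[0] else labels[0]
        mask[i] = True
    counts = _confusion(y, preds.astype(str), pos)
    return counts, figures_of_merit(counts)


def figures_of_merit(c: ConfusionCounts) -> FiguresOfMerit:
    """Exact sensitivity/specificity/accuracy percentages from the counts."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: TP + FN = 0")
    if c.TN + c.FP == 0:
        raise UndefinedMetricError("specificity undefined: TN + FP = 0")
    sen = Fraction(c.TP, c.TP + c.FN) * 100
    spe = Fraction(c.TN, c.TN + c.FP) * 100
    acc = Fraction(c.TP + c.TN, c.total) * 100
    return FiguresOfMerit(
        sensitivity=float(sen), specificity=float(spe), accuracy=float(acc)
    )


def evaluate_split(
    X_train: np.ndarray,
    y_train,
    X_test: np.ndarray | None,
    y_test,
    indices,
    positive_class: str | None = None,
) -> dict:
    """Cross-validated training figures plus single-fit test figures.

    Returns a report dict with the CV and test confusion tables and figures
    of merit, the fitted model, and per-row discriminant scores flagged
    train/test for plotting.  With an empty test partition the report
    carries ``test: None`` and an explicit ``test_absent`` flag.
    """
    indices = [int(i) for i in indices]
    cv_counts, cv_fom = loo_cv(X_train, y_train, indices, positive_class)
    model = fit_lda(X_train, y_train, indices, positive_class)
    train_scores = score(model, np.atleast_2d(np.asarray(X_train))[:, indices])
    report = {
        "indices": indices,
        "model": model,
        "cv": {"counts": cv_counts, "fom": cv_fom},
        "scores": [
            {"partition": "train", "true_class": str(c), "score": float(s)}
            for c, s in zip(y_train, train_scores)
        ],
    }
    if X_test is None or np.atleast_2d(np.asarray(X_test)).shape[0] == 0:
        report["test"] = None
        report["test_absent"] = True
        return report
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    test_scores = score(model, X_test[:, indices])
    y_pred = predict(model, X_test[:, indices])
    test_counts = _confusion(np.asarray([str(c) for c in y_test]), y_pred, model.positive_class)
    report["test"] = {"counts": test_counts, "fom": figures_of_merit(test_counts)}
    report["test_absent"] = False
    report["scores"].extend(
        {"partition": "test", "true_class": str(c), "score": float(s)}
        for c, s in zip(y_test, test_scores)
    )
    return report
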