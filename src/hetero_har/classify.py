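"""SVM classification with and without geodesic-flow-kernel adaptation.

:class:`GFKTransferClassifier` is the adaptation arm: both domains are
z-scored with their own statistics, the subspace dimension is chosen with
the subspace disagreement measure, the closed-form geodesic kernel G is
built from the two PCA subspaces, and a precomputed-kernel SVM (one-vs-one)
is trained on x_i^T G x_j over the labelled source windows.
:class:`NoAdaptationSVC` is the benchmark arm: a plain linear-kernel SVM
trained directly on the source domain, with no target information (the
source-only model that comparative adaptation studies benchmark against).

Evaluation follows the undefined-F1 bookkeeping convention of comparative
HAR tables: a task whose precision or recall denominator is zero gets an
undefined ("-") F1 rather than 0, and the overall (macro) F1 is undefined
whenever any per-task F1 is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .features import DomainDataset
from .gfk import geodesic_kernel, kernel_dot, pca_basis, principal_angles, select_dimension
from .synth import TASKS


def _domain_scale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    return mean, np.where(sd < 1e-12, 1.0, sd)


class GFKTransferClassifier(ClassifierMixin, BaseEstimator):
    """SVM over the geodesic flow kernel between source and target domains.

    Parameters
    ----------
    C
        SVM regularization strength.
    subspace_dim
        ``"auto"`` selects d with the subspace disagreement measure;
        an integer fixes it.
    d_max
        Optional cap on the candidate dimension; the structural cap
        ``floor(min(D, n_S - 1, n_T - 1) / 2)`` always applies.

    The estimator is transductive: the unlabelled target domain must be
    supplied at fit time (it defines the target subspace and scaling), and
    ``predict`` is intended for target-domain features.
    """

    def __init__(self, C: float = 1.0, subspace_dim: int | str = "auto",
                 d_max: Optional[int] = None):
        self.C = C
        self.subspace_dim = subspace_dim
        self.d_max = d_max

    def fit(self, X, y, X_target=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X_target is None:
            raise ValueError("X_target (unlabelled target features) is required")
        X_target = np.asarray(X_target, dtype=float)
        if X.shape[1] != X_target.shape[1]:
            raise ValueError("source and target feature dimensions differ")
        if np.unique(y).size < 2:
            raise ValueError("source labels must cover at least 2 classes")
        self.source_mean_, self.source_scale_ = _domain_scale(X)
        self.target_mean_, self.target_scale_ = _domain_scale(X_target)
        Xs = (X - self.source_mean_) / self.source_scale_
        Xt = (X_target - self.target_mean_) / self.target_scale_
        D = X.shape[1]
        cap = min(D, Xs.shape[0] - 1, Xt.shape[0] - 1) // 2
        if cap < 1:
            raise ValueError("domains too small for a subspace")
        if self.subspace_dim == "auto":
            d_max = cap if self.d_max is None else min(self.d_max, cap)
            self.sdm_profile_ = select_dimension(Xs, Xt, d_max)
            self.d_ = self.sdm_profile_.d_star
        else:
            self.d_ = int(self.subspace_dim)
            if not 1 <= self.d_ <= cap:
                raise ValueError(f"subspace_dim must be in [1, {cap}]")
            self.sdm_profile_ = None
        PS = pca_basis(Xs, self.d_)
        PT = pca_basis(Xt, self.d_)
        self.kernel_ = geodesic_kernel(principal_angles(PS, PT), PS)
        self.Xs_ = Xs
        K = kernel_dot(self.kernel_, Xs, Xs)
        self.svc_ = SVC(kernel="precomputed", C=self.C)
        self.svc_.fit(K, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Xt = (X - self.target_mean_) / self.target_scale_
        return self.svc_.predict(kernel_dot(self.kernel_, Xt, self.Xs_))


class NoAdaptationSVC(ClassifierMixin, BaseEstimator):
    """Linear-kernel SVM benchmark trained directly on the source domain.

    The source-only model of comparative adaptation studies: features are
    z-scored with the *source* statistics both at fit and at predict time,
    so no information about the target distribution enters the benchmark.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("source labels must cover at least 2 classes")
        self.source_mean_, self.source_scale_ = _domain_scale(X)
        Xs = (X - self.source_mean_) / self.source_scale_
        self.svc_ = SVC(kernel="linear", C=self.C)
        self.svc_.fit(Xs, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.svc_.predict((X - self.source_mean_) / self.source_scale_)


def fit_predict_da(
    source: DomainDataset,
    target: DomainDataset,
    svm_C: float = 1.0,
    d_max: Optional[int] = None,
) -> np.ndarray:
    """Adaptation arm: GFK + precomputed-kernel SVM, target labels predicted."""
    if source.y is None:
        raise ValueError("source domain must be labelled")
    clf = GFKTransferClassifier(C=svm_C, d_max=d_max)
    clf.fit(source.X, source.y, X_target=target.X)
    return clf.predict(target.X)


def fit_predict_baseline(
    source: DomainDataset,
    target: DomainDataset,
    svm_C: float = 1.0,
) -> np.ndarray:
    """Benchmark arm: source-only linear SVM, no target information."""
    if source.y is None:
        raise ValueError("source domain must be labelled")
    clf = NoAdaptationSVC(C=svm_C)
    clf.fit(source.X, source.y)
    return clf.predict(target.X)


@dataclass
class EvaluationReport:
    """Per-task F1 (None = undefined "-"), overall F1, accuracy, confusion.

    ``rod_mean`` carries the mean ROD of the candidate sources when the
    experiment used ROD-based selection.
    """

    task_f1: dict[str, Optional[float]]
    overall_f1: Optional[float]
    accuracy: float
    confusion: pd.DataFrame
    rod_mean: Optional[float] = None
    rod_selected_mean: Optional[float] = None

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            t: ("-" if f1 is None else round(f1, 4)) for t, f1 in self.task_f1.items()
        }
        row["overall_f1"] = "-" if self.overall_f1 is None else round(self.overall_f1, 4)
        row["accuracy"] = round(self.accuracy, 4)
        if self.rod_mean is not None:
            row["rod_mean"] = round(self.rod_mean, 4)
        return row


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    task_vocabulary: Sequence[str] = TASKS,
) -> EvaluationReport:
    """Score predictions with the undefined-F1 ("-") convention.

    Per-task F1 = 2PR/(P+R); a task whose precision denominator (predicted
    count) or recall denominator (true count) is zero is undefined.  The
    overall F1 (unweighted mean) is undefined if any per-task F1 is.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    vocab = list(task_vocabulary)
    unknown = (set(y_true) | set(y_pred)) - set(vocab)
    if unknown:
        raise ValueError(f"labels outside the vocabulary: {sorted(unknown)}")
    index = {t: i for i, t in enumerate(vocab)}
    cm = np.zeros((len(vocab), len(vocab)), dtype=int)
    for yt, yp in zip(y_true, y_pred):
        cm[index[yt], index[yp]] += 1
    task_f1: dict[str, Optional[float]] = {}
    for i, task in enumerate(vocab):
        tp = cm[i, i]
        pred_n = cm[:, i].sum()
        true_n = cm[i, :].sum()
        if pred_n == 0 or true_n == 0:
            task_f1[task] = None
            continue
        precision = tp / pred_n
        recall = tp / true_n
        task_f1[task] = (
            0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        )
    defined = [f1 for f1 in task_f1.values() if f1 is not None]
    overall_f1 = (
        None if len(defined) < len(vocab) else float(np.mean(defined))
    )
    accuracy = float(np.mean(y_true == y_pred)) if y_true.size else 0.0
    confusion = pd.DataFrame(cm, index=vocab, columns=vocab)
    return EvaluationReport(
        task_f1=task_f1,
        overall_f1=overall_f1,
        accuracy=accuracy,
        confusion=confusion,
    )
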