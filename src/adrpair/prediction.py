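"""Per-ADR binary classification machinery: stratified cross-validation
folds, PCA dimension reduction fitted on training rows only, classifier
training, and pooled-out-of-fold evaluation with macro averaging."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

CLASSIFIERS = ("svm", "logreg", "knn", "rf")

METRICS = ("precision", "recall", "accuracy", "f1", "auc")


class DegenerateLabelsError(ValueError):
    """Training labels contain a single class."""


@dataclass
class AdrDataset:
    """Labelled drug pairs for one ADR, rows aligned with the matrix."""

    adr_id: str
    pairs: list[tuple[str, str]]
    labels: np.ndarray  # 1 = known positive, 0 = selected negative
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels) or self.matrix.shape[0] != len(self.labels):
            raise ValueError("pairs, labels and matrix rows must align")
        pos = {p for p, y in zip(self.pairs, self.labels) if y == 1}
        neg = {p for p, y in zip(self.pairs, self.labels) if y == 0}
        if pos & neg:
            raise ValueError(f"{self.adr_id}: positives and negatives overlap")


@dataclass
class ReducedSpace:
    """A fitted centered linear projection (PCA loadings + mean)."""

    pca: PCA

    @property
    def pcn(self) -> int:
        return int(self.pca.n_components_)

    def transform(self, X) -> np.ndarray:
        if sp.issparse(X):
            X = np.asarray(X.todense())
        return self.pca.transform(X)


def split_folds(n_samples: int, labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Assign each sample to one of k near-equal, label-stratified test folds.

    Deterministic for a given seed.  Returns an int array of fold indices.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n_samples:
        raise ValueError(f"k={k} exceeds sample count {n_samples}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n_samples, dtype=int)
    for fold, (_, test_ix) in enumerate(skf.split(np.zeros(n_samples), labels)):
        assignment[test_ix] = fold
    return assignment


def fit_reduce(train_matrix, pcn: int, seed: int = 0) -> ReducedSpace:
    """Fit a PCA projection with ``pcn`` components on training rows only.

    Binary pair vectors are dense-ified for the decomposition; the
    projection maximises retained variance after centering.
    """
    if sp.issparse(train_matrix):
        train_matrix = np.asarray(train_matrix.todense())
    train_matrix = np.asarray(train_matrix, dtype=float)
    limit = min(train_matrix.shape)
    if pcn > limit:
        raise ValueError(
            f"pcn={pcn} exceeds min(n_samples, n_features)={limit} of the training matrix"
        )
    pca = PCA(n_components=pcn, svd_solver="full", random_state=seed)
    pca.fit(train_matrix)
    return ReducedSpace(pca=pca)


def make_classifier(algo: str, seed: int):
    """Library-default classifiers; stochastic ones are seeded."""
    if algo == "svm":
        return SVC(random_state=seed)  # RBF kernel, C=1; margin scores
    if algo == "logreg":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if algo == "knn":
        return KNeighborsClassifier()
    if algo == "rf":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {algo!r}; choose from {CLASSIFIERS}")


def train_classifier(train_features: np.ndarray, train_labels: np.ndarray, algo: str, seed: int = 0):
    """Fit a binary classifier producing both a hard label (``predict``)
    and a continuous score (``decision_function`` or positive-class
    probability)."""
    train_labels = np.asarray(train_labels)
    if len(np.unique(train_labels)) < 2:
        raise DegenerateLabelsError("training set contains a single class")
    clf = make_classifier(algo, seed)
    clf.fit(train_features, train_labels)
    return clf


def decision_scores(clf, features: np.ndarray) -> np.ndarray:
    """Continuous ranking scores: margin for margin classifiers, else the
    positive-class probability."""
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(features), dtype=float)
    proba = clf.predict_proba(features)
    pos_col = list(clf.classes_).index(1)
    return np.asarray(proba[:, pos_col], dtype=float)


def binary_metrics(y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray) -> dict:
    """Precision/recall/accuracy/F1 from hard labels, AUC from scores.

    AUC is ``None`` (excluded from macro averaging) when the pooled truth
    has a single class.
    """
    out = {
        "precision": precision_score(y_true, y_pred, zero_division=0),
        "recall": recall_score(y_true, y_pred, zero_division=0),
        "accuracy": accuracy_score(y_true, y_pred),
        "f1": f1_score(y_true, y_pred, zero_division=0),
    }
    if len(np.unique(y_true)) < 2:
        logger.warning("single-class truth: AUC undefined, reported as missing")
        out["auc"] = None
    else:
        out["auc"] = float(roc_auc_score(y_true, y_score))
    return {k: (None if v is None else float(v)) for k, v in out.items()}


@dataclass
class EvalReport:
    """Per-ADR metrics plus their unweighted macro averages and a config echo."""

    per_adr: dict[str, dict]
    config: dict = field(default_factory=dict)
    fold_assignments: dict[str, list[int]] = field(default_factory=dict)

    @property
    def macro(self) -> dict:
        out = {}
        for m in METRICS:
            vals = [r[m] for r in self.per_adr.values() if r.get(m) is not None]
            out[m] = float(np.mean(vals)) if vals else None
        return out

    def to_frame(self):
        import pandas as pd

        rows = [{"adr": adr, **{m: r.get(m) for m in METRICS}} for adr, r in sorted(self.per_adr.items())]
        rows.append({"adr": "MACRO", **self.macro})
        return pd.DataFrame(rows)


def evaluate(
    truths: Mapping[str, np.ndarray],
    predictions: Mapping[str, np.ndarray],
    scores: Mapping[str, np.ndarray],
    config: dict | None = None,
    fold_assignments: Mapping[str, Sequence[int]] | None = None,
) -> EvalReport:
    """Pool each ADR's out-of-fold predictions into one metric row and
    macro-average across ADRs."""
    per_adr = {}
    for adr in truths:
        per_adr[adr] = binary_metrics(
            np.asarray(truths[adr]), np.asarray(predictions[adr]), np.asarray(scores[adr])
        )
    return EvalReport(
        per_adr=per_adr,
        config=dict(config or {}),
        fold_assignments={k: list(map(int, v)) for k, v in (fold_assignments or {}).items()},
    )


def cross_validate_adr(
    dataset: AdrDataset,
    pcn: int,
    algo: str,
    k: int,
    seed: int,
    clamp_pcn: bool = True,
) -> tuple[dict, np.ndarray, np.ndarray, np.ndarray]:
    """k-fold CV for one ADR with the reducer and classifier fit inside
    each training fold (no leakage).

    Returns (metrics dict, fold assignment, pooled predictions, pooled scores).
    """
    y = dataset.labels
    folds = split_folds(len(y), y, k, seed)
    y_pred = np.empty(len(y), dtype=int)
    y_score = np.empty(len(y), dtype=float)
    X = dataset.matrix
    for fold in range(k):
        test = folds == fold
        train = ~test
        n_train = int(train.sum())
        fold_pcn = pcn
        if clamp_pcn:
            feasible = min(n_train, X.shape[1])
            if pcn > feasible:
                logger.warning(
                    "%s fold %d: pcn clamped %d -> %d", dataset.adr_id, fold, pcn, feasible
                )
                fold_pcn = feasible
        space = fit_reduce(X[train], fold_pcn, seed=seed)
        Z_train = space.transform(X[train])
        Z_test = space.transform(X[test])
        clf = train_classifier(Z_train, y[train], algo, seed=seed + fold)
        y_pred[test] = clf.predict(Z_test)
        y_score[test] = decision_scores(clf, Z_test)
    return binary_metrics(y, y_pred, y_score), folds, y_pred, y_score
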