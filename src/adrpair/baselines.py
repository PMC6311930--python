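"""Comparison methods: random negative sampling (RGNS), random label
assignment, and one-class SVM evaluated on random vs. screened negatives.

Every baseline reuses the main pipeline's featurization, folds and metric
suite so that differences in the comparison table come only from how the
class-0 samples (or the decision rule) are obtained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import AbstractSet, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from . import featurize, scoring
from .model import AdrPairModel, _spawn_seeds
from .prediction import (
    AdrDataset,
    EvalReport,
    METRICS,
    binary_metrics,
    cross_validate_adr,
    fit_reduce,
    split_folds,
)

logger = logging.getLogger(__name__)

METHODS = ("hcns", "rgns", "random_assign", "ocsvm_random", "ocsvm_screen")


@dataclass(frozen=True)
class BaselineConfig:
    method: str
    repeats: int = 5
    nsr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def sample_random_negatives(
    all_pairs: Sequence[tuple[str, str]],
    positives: AbstractSet[tuple[str, str]],
    count: int,
    seed: int,
) -> list[tuple[str, str]]:
    """Uniform sample without replacement from the non-positive pairs."""
    candidates = [p for p in all_pairs if p not in positives]
    if count > len(candidates):
        raise scoring.CapacityError(
            f"requested {count} negatives but only {len(candidates)} candidates"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=count, replace=False)
    return [candidates[i] for i in sorted(idx)]


def random_assign(train_labels: np.ndarray, test_size: int, seed: int) -> np.ndarray:
    """Assign label 1 to round(prevalence * test_size) random test samples.

    The prevalence is the ratio of label 1 in the training set; the rest of
    the test set gets 0.  This is the chance-level reference: against
    balanced truth its expected accuracy is p^2 + (1-p)^2.
    """
    if test_size < 1:
        raise ValueError("test_size must be >= 1")
    train_labels = np.asarray(train_labels)
    prevalence = float(np.mean(train_labels == 1)) if len(train_labels) else 0.0
    n_pos = round(prevalence * test_size)
    rng = np.random.default_rng(seed)
    out = np.zeros(test_size, dtype=int)
    out[rng.choice(test_size, size=n_pos, replace=False)] = 1
    return out


def _mean_reports(reports: Sequence[EvalReport]) -> EvalReport:
    """Average per-ADR metrics across repeated runs (None-aware)."""
    adrs = sorted(reports[0].per_adr)
    per_adr = {}
    for adr in adrs:
        row = {}
        for m in METRICS:
            vals = [r.per_adr[adr][m] for r in reports if r.per_adr[adr].get(m) is not None]
            row[m] = float(np.mean(vals)) if vals else None
        per_adr[adr] = row
    return EvalReport(per_adr=per_adr, config=dict(reports[0].config))


def run_rgns(model: AdrPairModel, repeats: int = 5, seed: int | None = None) -> EvalReport:
    """The main pipeline with uniformly random (instead of screened)
    negatives, averaged over ``repeats`` reseeded draws."""
    cfg = model.config
    base_seed = cfg.seed if seed is None else seed
    positives = model.positives_by_adr()
    adrs = sorted(a for a, p in positives.items() if len(p) >= cfg.min_positives)
    all_pairs = list(zip(model.ranked_pairs["drug_a"], model.ranked_pairs["drug_b"]))
    reports = []
    draw_seeds = _spawn_seeds(base_seed, repeats, "rgns")
    cv_seeds = dict(zip(adrs, _spawn_seeds(base_seed, len(adrs), "cv")))
    for r in range(repeats):
        per_adr = {}
        for adr in adrs:
            pos = positives[adr]
            negs = sample_random_negatives(
                all_pairs, pos, round(cfg.nsr * len(pos)),
                seed=draw_seeds[r] + _spawn_seeds(0, len(adrs), adr)[0] % 10_000,
            )
            ds = model.build_adr_dataset(adr, negatives=negs)
            metrics, _, _, _ = cross_validate_adr(ds, cfg.pcn, cfg.algo, cfg.folds, cv_seeds[adr])
            per_adr[adr] = metrics
        reports.append(EvalReport(per_adr=per_adr, config=cfg.to_dict()))
    return _mean_reports(reports)


def run_random_assign(model: AdrPairModel, repeats: int = 5, seed: int | None = None) -> EvalReport:
    """Chance-level baseline on the HCNS datasets: labels assigned at random
    in each test fold at the training prevalence; no continuous score, so
    the random labels double as scores (AUC ~ 0.5)."""
    cfg = model.config
    base_seed = cfg.seed if seed is None else seed
    positives = model.positives_by_adr()
    adrs = sorted(a for a, p in positives.items() if len(p) >= cfg.min_positives)
    cv_seeds = dict(zip(adrs, _spawn_seeds(base_seed, len(adrs), "cv")))
    rep_seeds = _spawn_seeds(base_seed, repeats, "random_assign")
    reports = []
    for r in range(repeats):
        per_adr = {}
        for i, adr in enumerate(adrs):
            ds = model.build_adr_dataset(adr)
            y = ds.labels
            folds = split_folds(len(y), y, cfg.folds, cv_seeds[adr])
            y_pred = np.empty(len(y), dtype=int)
            for fold in range(cfg.folds):
                test = folds == fold
                y_pred[test] = random_assign(
                    y[~test], int(test.sum()), seed=rep_seeds[r] + 7919 * i + fold
                )
            per_adr[adr] = binary_metrics(y, y_pred, y_pred.astype(float))
        reports.append(EvalReport(per_adr=per_adr, config=cfg.to_dict()))
    return _mean_reports(reports)


def one_class_fit_eval(
    positives_matrix,
    test_sets: Mapping[str, tuple],
    seed: int = 0,
) -> dict[str, dict]:
    """Train a one-class SVM on positive pair vectors only and evaluate on
    each named test set (matrix, labels) with the standard metric suite.

    Default RBF kernel with the library's standard nu and gamma.
    """
    if positives_matrix.shape[0] == 0:
        raise ValueError("one-class training requires at least one positive sample")
    pcn = min(positives_matrix.shape[0], positives_matrix.shape[1])
    space = fit_reduce(positives_matrix, pcn, seed=seed)
    oc = OneClassSVM()  # rbf kernel, nu=0.5, gamma='scale'
    oc.fit(space.transform(positives_matrix))
    out = {}
    for name, (X, y) in test_sets.items():
        Z = space.transform(X)
        pred = (oc.predict(Z) == 1).astype(int)
        score = oc.decision_function(Z)
        out[name] = binary_metrics(np.asarray(y), pred, np.asarray(score, dtype=float))
    return out


def run_ocsvm(
    model: AdrPairModel,
    screened: bool,
    repeats: int = 5,
    seed: int | None = None,
) -> EvalReport:
    """One-class SVM per ADR: train on that ADR's positive pairs only, test
    on held-out positives plus nsr=1 negatives that are either uniformly
    random (averaged over repeats) or the screened low-score prefix."""
    cfg = model.config
    base_seed = cfg.seed if seed is None else seed
    positives = model.positives_by_adr()
    adrs = sorted(a for a, p in positives.items() if len(p) >= cfg.min_positives)
    all_pairs = list(zip(model.ranked_pairs["drug_a"], model.ranked_pairs["drug_b"]))
    n_rep = 1 if screened else repeats
    rep_seeds = _spawn_seeds(base_seed, n_rep, "ocsvm")
    reports = []
    for r in range(n_rep):
        per_adr = {}
        for adr in adrs:
            pos = sorted(positives[adr])
            if screened:
                negs = scoring.select_negatives(model.ranked_pairs, set(pos), cfg.nsr)
            else:
                negs = sample_random_negatives(
                    all_pairs, set(pos), round(cfg.nsr * len(pos)), seed=rep_seeds[r]
                )
            pos_matrix = featurize.build_matrix(pos, model.vectors)
            test_pairs = pos + list(negs)
            test_y = np.array([1] * len(pos) + [0] * len(negs))
            test_X = featurize.build_matrix(test_pairs, model.vectors)
            res = one_class_fit_eval(
                pos_matrix, {"test": (test_X, test_y)}, seed=base_seed
            )
            per_adr[adr] = res["test"]
        reports.append(EvalReport(per_adr=per_adr, config=cfg.to_dict()))
    return _mean_reports(reports)


def run_comparison(
    model: AdrPairModel,
    methods: Sequence[str] = METHODS,
    repeats: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the selected methods on identical data and collect one
    macro-metric row per method (columns: AUC, F1, precision, recall,
    accuracy)."""
    if not methods:
        raise ValueError("configure at least one method")
    rows = []
    for method in methods:
        if method == "hcns":
            report = model.fit(seed=seed).report
        elif method == "rgns":
            report = run_rgns(model, repeats=repeats, seed=seed)
        elif method == "random_assign":
            report = run_random_assign(model, repeats=repeats, seed=seed)
        elif method == "ocsvm_random":
            report = run_ocsvm(model, screened=False, repeats=repeats, seed=seed)
        elif method == "ocsvm_screen":
            report = run_ocsvm(model, screened=True, repeats=repeats, seed=seed)
        else:
            raise ValueError(f"unknown method {method!r}")
        macro = report.macro
        rows.append(
            {
                "method": method,
                "macro_auc": macro["auc"],
                "macro_f1": macro["f1"],
                "macro_precision": macro["precision"],
                "macro_recall": macro["recall"],
                "macro_accuracy": macro["accuracy"],
            }
        )
    return pd.DataFrame(rows)
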