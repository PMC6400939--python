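"""Gaussian-kernel SVM diagnosis from the 12 optical predictors.

Two binary tasks are supported — tumor vs. mammoplasty (margin assessment)
and tumor vs. benign lesion (biopsy triage) — with tumor as the positive
class throughout.  Feature selection is exhaustive over all single features
and all pairs (12 + 66 = 78 candidate sets), scored by the AUC of pooled
out-of-fold decision values from seeded stratified k-fold cross-validation.
Per fold, features are standardised on the training split only and an RBF
(Gaussian) kernel soft-margin SVM is fitted; the kernel bandwidth defaults
to the median pairwise distance heuristic on the training split.

The ROC is swept over the unique out-of-fold scores; the operating point
maximises Youden's J = sensitivity + specificity - 1, with ties broken
toward higher specificity (a conservative rule-in choice for a cancer
diagnostic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FEATURE_BLOCKS, FEATURE_NAMES

logger = logging.getLogger(__name__)


@dataclass
class KernelConfig:
    """Soft-margin RBF-SVM hyperparameters.

    ``gamma="median"`` sets gamma = 1 / (2 m^2) with m the median pairwise
    Euclidean distance between standardised training rows.
    """

    C: float = 1.0
    gamma: float | str = "median"


@dataclass
class LabeledFeatureSet:
    """Aligned feature matrix, binary labels and biopsy identifiers."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    biopsy_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, d = self.X.shape
        if len(self.y) != n or len(self.biopsy_ids) != n:
            raise ValueError("rows of X must align with y and biopsy_ids")
        if len(self.feature_names) != d:
            raise ValueError("feature_names must match X columns")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        if set(np.unique(self.y)) != {0, 1}:
            raise ValueError("both classes (0 and 1) must be present")


@dataclass
class ROCResult:
    """ROC swept over descending score thresholds (score >= t -> positive)."""

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass
class SelectionReport:
    """Exhaustive singleton/pair feature search results."""

    candidate_sets: list[tuple[tuple[str, ...], float]]
    best_set: tuple[str, ...]
    best_auc: float
    cv_seed: int


@dataclass
class ClassifierReport:
    """Everything one diagnostic task produces."""

    task: str
    selection: SelectionReport
    roc: ROCResult
    operating_point: OperatingPoint
    scores: np.ndarray
    y: np.ndarray
    biopsy_ids: tuple[str, ...]
    block_aucs: dict[str, float] = field(default_factory=dict)


def standardize(
    train_X: np.ndarray, apply_X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-score columns by training mean/SD (n-1); no leakage into apply_X."""
    train_X = np.asarray(train_X, dtype=float)
    apply_X = np.asarray(apply_X, dtype=float)
    if train_X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance training column(s) at index {zero.tolist()}")
    return (train_X - mu) / sd, (apply_X - mu) / sd, mu, sd


def _resolve_gamma(train_Z: np.ndarray, cfg: KernelConfig) -> float:
    if isinstance(cfg.gamma, (int, float)):
        return float(cfg.gamma)
    if cfg.gamma != "median":
        raise ValueError(f"unknown gamma setting {cfg.gamma!r}")
    d = pdist(train_Z)
    d = d[d > 0]
    if d.size == 0:
        return 1.0 / train_Z.shape[1]
    m = float(np.median(d))
    return 1.0 / (2.0 * m * m)


_fold_warnings: set[tuple[int, int]] = set()


def effective_folds(y: np.ndarray, k: int) -> int:
    """Reduce k to the minority class size when the cohort is too small.

    Stratified 10-fold CV is impossible with e.g. 6 negative-control
    biopsies; the fold count is capped at the minority count (warning
    logged once per (k, minority) combination) so every fold keeps both
    classes.
    """
    minority = int(np.bincount(np.asarray(y, dtype=int)).min())
    if k > minority:
        if (k, minority) not in _fold_warnings:
            _fold_warnings.add((k, minority))
            logger.warning("reducing CV folds from %d to minority class size %d", k, minority)
        return minority
    return k


def cv_scores(
    data: LabeledFeatureSet,
    feature_subset: tuple[str, ...] | list[str],
    k: int = 10,
    kernel_config: KernelConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold RBF-SVM decision values, one per biopsy.

    Stratified k-fold with a fixed shuffle seed; standardisation and kernel
    bandwidth are derived from each training split only.  Scores are
    oriented so that higher means more tumor-like.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    kernel_config = kernel_config or KernelConfig()
    idx = [data.feature_names.index(f) for f in feature_subset]
    X = data.X[:, idx]
    y = data.y
    k_eff = effective_folds(y, k)
    if k_eff < 2:
        raise ValueError("minority class too small for cross-validation")

    scores = np.empty(len(y))
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a training fold lost a class; use smaller k")
        train_Z, test_Z, _, _ = standardize(X[train_idx], X[test_idx])
        gamma = _resolve_gamma(train_Z, kernel_config)
        clf = SVC(C=kernel_config.C, kernel="rbf", gamma=gamma)
        clf.fit(train_Z, y[train_idx])
        dec = clf.decision_function(test_Z)
        # decision_function is oriented toward clf.classes_[1]; flip if needed
        if clf.classes_[1] == 0:
            dec = -dec
        scores[test_idx] = dec
    return scores


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC over unique score thresholds, AUC by the trapezoidal rule.

    The trapezoid over tied-score steps makes the AUC equal to the pairwise
    concordance probability with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred_pos = scores >= t
        sens[i] = (pred_pos & (labels == 1)).sum() / n_pos
        spec[i] = (~pred_pos & (labels == 0)).sum() / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCResult(thresholds=thresholds, sens=sens, spec=spec, auc=auc)


def youden_optimum(roc: ROCResult) -> OperatingPoint:
    """Threshold maximising J = sens + spec - 1; ties -> higher specificity."""
    j = roc.sens + roc.spec - 1.0
    jmax = j.max()
    tied = np.nonzero(j == jmax)[0]
    best = tied[np.lexsort((roc.thresholds[tied], roc.spec[tied]))[-1]]
    return OperatingPoint(
        threshold=float(roc.thresholds[best]),
        sensitivity=float(roc.sens[best]),
        specificity=float(roc.spec[best]),
        youden_j=float(jmax),
    )


def select_features(
    data: LabeledFeatureSet,
    k: int = 10,
    kernel_config: KernelConfig | None = None,
    seed: int = 0,
) -> SelectionReport:
    """Exhaustive search over all singletons then all pairs by CV AUC.

    Ties favour fewer features, then lexicographic feature order — the
    evaluation order below, so the first maximum wins.
    """
    names = data.feature_names
    if len(names) < 2:
        raise ValueError("need at least 2 features")
    if len(data.y) < 4:
        raise ValueError("too few biopsies for cross-validated selection")

    singletons = [(f,) for f in sorted(names)]
    pairs = [tuple(p) for p in combinations(sorted(names), 2)]
    candidates: list[tuple[tuple[str, ...], float]] = []
    best_set, best_auc = None, -np.inf
    for subset in singletons + pairs:
        scores = cv_scores(data, subset, k=k, kernel_config=kernel_config, seed=seed)
        auc = roc_auc(scores, data.y).auc
        candidates.append((subset, auc))
        if auc > best_auc:
            best_set, best_auc = subset, auc
    return SelectionReport(
        candidate_sets=candidates, best_set=best_set, best_auc=float(best_auc),
        cv_seed=seed,
    )


def feature_table_to_set(df: pd.DataFrame, task: str) -> LabeledFeatureSet:
    """Subset a features table to one binary task (positive class: tumor)."""
    negatives = {"tumor_vs_mammoplasty": "mammoplasty", "tumor_vs_benign": "benign"}
    if task not in negatives:
        raise ValueError(f"unknown task {task!r}")
    neg = negatives[task]
    sub = df[df["tissue_class"].isin(["tumor", neg])]
    if sub["tissue_class"].nunique() < 2:
        raise ValueError(f"task {task!r}: one of the classes is missing")
    return LabeledFeatureSet(
        X=sub[list(FEATURE_NAMES)].to_numpy(dtype=float),
        y=(sub["tissue_class"] == "tumor").astype(int).to_numpy(),
        feature_names=FEATURE_NAMES,
        biopsy_ids=tuple(sub["biopsy_id"]),
    )


def run_task(
    features_df: pd.DataFrame,
    task: str,
    k: int = 10,
    kernel_config: KernelConfig | None = None,
    seed: int = 0,
) -> ClassifierReport:
    """Full diagnostic task: selection, CV scoring, ROC, Youden point.

    Also reports the cross-validated AUC of each of the four fixed predictor
    blocks (CDF-fit and summary features, all pixels and top 1%).
    """
    data = feature_table_to_set(features_df, task)
    selection = select_features(data, k=k, kernel_config=kernel_config, seed=seed)
    scores = cv_scores(data, selection.best_set, k=k, kernel_config=kernel_config, seed=seed)
    roc = roc_auc(scores, data.y)
    op = youden_optimum(roc)
    block_aucs = {
        block: roc_auc(
            cv_scores(data, feats, k=k, kernel_config=kernel_config, seed=seed), data.y
        ).auc
        for block, feats in FEATURE_BLOCKS.items()
    }
    return ClassifierReport(
        task=task, selection=selection, roc=roc, operating_point=op,
        scores=scores, y=data.y, biopsy_ids=data.biopsy_ids, block_aucs=block_aucs,
    )
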