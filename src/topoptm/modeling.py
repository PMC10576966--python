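"""Feature selection, class balancing, classifier training and evaluation.

The modeling stage mirrors common practice for imbalanced site-prediction
data: NearMiss undersampling to a 1:1 class ratio, an F-score ranking of
features (between-class over within-class variance), incremental feature
selection by cross-validated MCC, and gradient-boosting / random-forest /
SVC classifiers with fixed hyperparameters.

Classifiers are scikit-learn estimators; the F-score, NearMiss rule and
the threshold-free metrics (MCC from the confusion table, rank-based AUC)
are implemented here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class ModelConfig:
    """Classifier kind + fixed hyperparameters.

    gbc: gradient boosting, 500 estimators.
    rfc: random forest, 370 estimators, out-of-bag scoring, sqrt feature
         subsampling.
    svc: RBF support-vector classifier, gamma='auto', probability outputs,
         features standardized inside each training fold.
    """

    kind: str = "gbc"
    seed: int = 0
    n_estimators: int | None = None

    def __post_init__(self):
        if self.kind not in ("gbc", "rfc", "svc"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    def build(self):
        if self.kind == "gbc":
            return GradientBoostingClassifier(
                n_estimators=self.n_estimators or 500, random_state=self.seed
            )
        if self.kind == "rfc":
            return RandomForestClassifier(
                n_estimators=self.n_estimators or 370,
                oob_score=True,
                max_features="sqrt",
                random_state=self.seed,
            )
        return make_pipeline(
            StandardScaler(),
            SVC(gamma="auto", probability=True, random_state=self.seed),
        )


@dataclass(frozen=True)
class FScoreRanking:
    scores: np.ndarray
    order: np.ndarray  # feature indices, scores non-increasing

    def top(self, m: int) -> np.ndarray:
        return self.order[:m]


@dataclass(frozen=True)
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    sp: float
    sn: float
    acc: float
    mcc: float
    auc: float
    folds: tuple["EvalReport", ...] = field(default_factory=tuple)

    @classmethod
    def from_counts(cls, tp, tn, fp, fn, auc, folds=()):
        sp, sn, acc, mcc = confusion_metrics(tp, tn, fp, fn)
        return cls(int(tp), int(tn), int(fp), int(fn),
                   sp, sn, acc, mcc, float(auc), tuple(folds))

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sp": self.sp, "sn": self.sn, "acc": self.acc,
            "mcc": self.mcc, "auc": self.auc,
            "folds": [f.to_dict() for f in self.folds],
        }


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "SUO":
        y = (y == "positive").astype(int)
    else:
        y = y.astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1 or negative/positive)")
    return y


def f_scores(features: np.ndarray, labels) -> FScoreRanking:
    """Per-feature F-score: squared deviations of the class means from the
    grand mean over the summed within-class sample variances (n−1 divisor).

    A feature with zero denominator (constant within both classes) scores 0.
    """
    X = np.asarray(features, dtype=float)
    y = _as_binary(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 samples in each class")
    pos, neg = X[y == 1], X[y == 0]
    grand = X.mean(axis=0)
    mp, mn = pos.mean(axis=0), neg.mean(axis=0)
    num = (mp - grand) ** 2 + (mn - grand) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    order = np.lexsort((np.arange(X.shape[1]), -scores))
    return FScoreRanking(scores, order)


def near_miss(features: np.ndarray, labels, n_neighbors: int = 3) -> np.ndarray:
    """NearMiss (version 1) undersampling: keep every minority sample and
    the |minority| majority samples with the smallest mean Euclidean
    distance to their ``n_neighbors`` nearest minority neighbors.

    Returns the sorted indices of the retained samples.  Ties are broken
    by sample index; a balanced input is returned unchanged.
    """
    X = np.asarray(features, dtype=float)
    y = _as_binary(labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) == 0:
        raise ValueError("minority class is empty")
    if n_pos == n_neg:
        return np.arange(len(y))
    minority = 1 if n_pos < n_neg else 0
    min_idx = np.nonzero(y == minority)[0]
    maj_idx = np.nonzero(y != minority)[0]
    k = min(n_neighbors, len(min_idx))
    nn = NearestNeighbors(n_neighbors=k).fit(X[min_idx])
    dists, _ = nn.kneighbors(X[maj_idx])
    mean_d = dists.mean(axis=1)
    pick = np.lexsort((maj_idx, mean_d))[: len(min_idx)]
    return np.sort(np.concatenate([min_idx, maj_idx[pick]]))


def confusion_metrics(tp, tn, fp, fn) -> tuple[float, float, float, float]:
    """Specificity, sensitivity, accuracy and MCC from confusion counts.

    Any zero factor in the MCC denominator yields MCC = 0; an undefined
    Sp or Sn (empty class) is reported as 0.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("no samples")
    sp = tn / (tn + fp) if tn + fp else 0.0
    sn = tp / (tp + fn) if tp + fn else 0.0
    acc = (tp + tn) / total
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn) - (fp * fn)) / math.sqrt(den) if den else 0.0
    return sp, sn, acc, mcc


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) formulation:
    the probability that a random positive outscores a random negative,
    ties counting one half."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _positive_proba(model, X) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = list(model.classes_) if hasattr(model, "classes_") else list(
        model[-1].classes_
    )
    return proba[:, classes.index(1)]


def cross_validate(
    features: np.ndarray,
    labels,
    cfg: ModelConfig,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross validation with pooled confusion counts and
    AUC computed on the pooled out-of-fold probabilities."""
    X = np.asarray(features, dtype=float)
    y = _as_binary(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > min(int(y.sum()), int((1 - y).sum())):
        raise ValueError("k exceeds the size of the smaller class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    counts = np.zeros(4, dtype=int)  # tp tn fp fn
    folds = []
    base = cfg.build()
    for train, test in skf.split(X, y):
        model = clone(base)
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        prob = _positive_proba(model, X[test])
        oof[test] = prob
        tp = int(np.sum((pred == 1) & (y[test] == 1)))
        tn = int(np.sum((pred == 0) & (y[test] == 0)))
        fp = int(np.sum((pred == 1) & (y[test] == 0)))
        fn = int(np.sum((pred == 0) & (y[test] == 1)))
        counts += (tp, tn, fp, fn)
        fold_auc = roc_auc(prob, y[test]) if 0 < y[test].sum() < len(test) else 0.5
        folds.append(EvalReport.from_counts(tp, tn, fp, fn, fold_auc))
    return EvalReport.from_counts(*counts, auc=roc_auc(oof, y), folds=folds)


def independent_test(
    features: np.ndarray,
    labels,
    cfg: ModelConfig,
    test_size: float = 0.3,
    repeats: int = 1,
    seed: int = 0,
) -> tuple[list[EvalReport], pd.DataFrame]:
    """Repeated stratified train/test splits at a fixed dividing ratio.

    Returns one report per repeat plus a mean ± standard-deviation summary
    over the repeats (columns sp/sn/acc/mcc/auc; rows mean, sd).
    """
    X = np.asarray(features, dtype=float)
    y = _as_binary(labels)
    if not 0 < test_size < 1:
        raise ValueError("test_size must be in (0, 1)")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    sss = StratifiedShuffleSplit(
        n_splits=repeats, test_size=test_size, random_state=seed
    )
    reports = []
    base = cfg.build()
    for train, test in sss.split(X, y):
        model = clone(base)
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        prob = _positive_proba(model, X[test])
        tp = int(np.sum((pred == 1) & (y[test] == 1)))
        tn = int(np.sum((pred == 0) & (y[test] == 0)))
        fp = int(np.sum((pred == 1) & (y[test] == 0)))
        fn = int(np.sum((pred == 0) & (y[test] == 1)))
        reports.append(
            EvalReport.from_counts(tp, tn, fp, fn, roc_auc(prob, y[test]))
        )
    metrics = pd.DataFrame(
        [(r.sp, r.sn, r.acc, r.mcc, r.auc) for r in reports],
        columns=["sp", "sn", "acc", "mcc", "auc"],
    )
    summary = pd.DataFrame(
        {"mean": metrics.mean(), "sd": metrics.std(ddof=1).fillna(0.0)}
    ).T
    return reports, summary


def incremental_selection(
    features: np.ndarray,
    labels,
    ranking: FScoreRanking,
    cfg: ModelConfig,
    k: int = 10,
    seed: int = 0,
    stride: int = 1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Grow the feature set along the F-score ranking, evaluating each
    prefix by k-fold CV; return the MCC-vs-size curve and the smallest
    prefix attaining the maximal MCC (first-max tie-break).

    ``stride`` evaluates every stride-th prefix size (plus the full set)
    for cheaper scans; the retrained models are independent at each size.
    """
    X = np.asarray(features, dtype=float)
    d = X.shape[1]
    sizes = list(range(1, d + 1, stride))
    if sizes[-1] != d:
        sizes.append(d)
    rows = []
    for m in sizes:
        rep = cross_validate(X[:, ranking.top(m)], labels, cfg, k=k, seed=seed)
        rows.append((m, rep.mcc, rep.auc))
    curve = pd.DataFrame(rows, columns=["n_features", "mcc", "auc"])
    best_m = int(curve.loc[curve["mcc"].idxmax(), "n_features"])
    return curve, ranking.top(best_m)


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted estimator with a format/version tag."""
    import joblib

    from . import __version__

    joblib.dump(
        {"format_version": 1, "package_version": __version__, "model": model},
        path,
    )


def load_model(path: str | Path):
    import joblib

    payload = joblib.load(path)
    if not isinstance(payload, dict) or "model" not in payload:
        raise ValueError(f"{path} is not a serialized model artifact")
    if payload.get("format_version") != 1:
        raise ValueError(
            f"unsupported model artifact version {payload.get('format_version')!r}"
        )
    return payload["model"]


def write_metrics_json(report: EvalReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve samples (fpr, tpr, threshold) over all score thresholds."""
    from sklearn.metrics import roc_curve

    y = _as_binary(labels)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
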