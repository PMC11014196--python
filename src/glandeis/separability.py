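"""Thyroid-vs-parathyroid separability from spectrum indices.

Two assessments mirror the study design:

* manual ROC per index — the classification threshold is swept over the
  pooled scores, TPR = TP/(TP+FN) and FPR = FP/(FP+TN) are accumulated
  at every threshold, and the AUC is the trapezoidal area.  Both label
  directions ("thyroid higher" and "parathyroid higher") are tested and
  the more favourable one reported;
* 20-fold cross-validated SVM / KNN / random-forest classification on
  all three indices jointly, reporting mean accuracy and mean AUC on
  identical fold splits, with no feature scaling or selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "ConfusionCounts",
    "ROCResult",
    "CVReport",
    "roc_auc",
    "best_direction_auc",
    "cross_validate_classifiers",
    "SeparabilityAnalysis",
    "SeparabilityResults",
]

DIRECTIONS = ("t>p", "p>t")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def tpr(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def fpr(self) -> float:
        return self.FP / (self.FP + self.TN)


@dataclass
class ROCResult:
    """Threshold sweep for one index and one direction."""

    index_name: str
    direction: str  # 't>p' or 'p>t'
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CVReport:
    """Cross-validated performance of one classifier."""

    classifier: str  # 'SVM' | 'KNN' | 'RFC'
    fold_auc: list[float]
    fold_accuracy: list[float]
    k: int
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))


def _validate_scores(scores_t, scores_p):
    scores_t = np.asarray(scores_t, dtype=float)
    scores_p = np.asarray(scores_p, dtype=float)
    if scores_t.size == 0 or scores_p.size == 0:
        raise ValueError("both gland groups must be non-empty")
    if not (np.all(np.isfinite(scores_t)) and np.all(np.isfinite(scores_p))):
        raise ValueError("scores must be finite")
    return scores_t, scores_p


def roc_auc(scores_thyroid, scores_parathyroid, direction: str, index_name: str = "") -> ROCResult:
    """Manual ROC for one index under a fixed direction.

    ``direction`` names the gland predicted to score higher; that gland
    is the positive class and a case is called positive when its score
    is at or above the threshold.  Thresholds sweep the midpoints of
    adjacent sorted unique pooled scores plus sentinels below and above
    all scores, anchoring the curve at (0,0) and (1,1).
    """
    scores_t, scores_p = _validate_scores(scores_thyroid, scores_parathyroid)
    if direction == "t>p":
        pos, neg = scores_t, scores_p
    elif direction == "p>t":
        pos, neg = scores_p, scores_t
    else:
        raise ValueError(f"direction must be one of {DIRECTIONS}")

    pooled = np.unique(np.concatenate([pos, neg]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    span = max(pooled[-1] - pooled[0], 1.0)
    thresholds = np.concatenate(
        [[pooled[0] - span], mids, [pooled[-1] + span]]
    )  # ascending; descending sweep walks (0,0) → (1,1)

    tpr, fpr = [], []
    for theta in thresholds[::-1]:
        counts = ConfusionCounts(
            TP=int(np.sum(pos >= theta)),
            FN=int(np.sum(pos < theta)),
            FP=int(np.sum(neg >= theta)),
            TN=int(np.sum(neg < theta)),
        )
        tpr.append(counts.tpr)
        fpr.append(counts.fpr)
    tpr = np.asarray(tpr)
    fpr = np.asarray(fpr)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        index_name=index_name,
        direction=direction,
        thresholds=thresholds[::-1],
        tpr=tpr,
        fpr=fpr,
        auc=auc,
    )


def best_direction_auc(scores_thyroid, scores_parathyroid, index_name: str = "") -> ROCResult:
    """The more favourable of the two label directions (AUC ≥ 0.5)."""
    results = [
        roc_auc(scores_thyroid, scores_parathyroid, d, index_name) for d in DIRECTIONS
    ]
    return max(results, key=lambda r: r.auc)


def _fold_auc(y_true: np.ndarray, score: np.ndarray) -> float:
    """AUC of a continuous positive-class score via the manual ROC."""
    return roc_auc(score[y_true == 1], score[y_true == 0], "t>p").auc


def cross_validate_classifiers(
    features: pd.DataFrame,
    labels,
    k: int = 20,
    seed: int = 0,
) -> list[CVReport]:
    """SVM, KNN and RFC on identical stratified k-fold splits.

    ``labels`` may be gland-name strings or binary; thyroid (or 1) is the
    positive class.  Raw features go in untouched — no scaling, no
    selection.  Fold AUC uses each classifier's continuous score: SVM's
    decision function, and the positive-class vote fraction for KNN and
    the random forest.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        y = (labels == "thyroid").astype(int)
    else:
        y = labels.astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")
    if len(X) < k:
        raise ValueError(f"need at least k={k} samples")

    models = {
        "SVM": SVC(kernel="rbf"),
        "KNN": KNeighborsClassifier(n_neighbors=5),
        "RFC": RandomForestClassifier(n_estimators=100, random_state=seed),
    }
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(splitter.split(X, y))
    reports = []
    for name, model in models.items():
        fold_auc, fold_acc = [], []
        for train, test in folds:
            if len(np.unique(y[train])) < 2:
                raise ValueError("a training fold contains a single class")
            model.fit(X[train], y[train])
            pred = model.predict(X[test])
            fold_acc.append(float(np.mean(pred == y[test])))
            if name == "SVM":
                score = model.decision_function(X[test])
            else:
                score = model.predict_proba(X[test])[:, list(model.classes_).index(1)]
            fold_auc.append(_fold_auc(y[test], np.asarray(score, dtype=float)))
        reports.append(
            CVReport(classifier=name, fold_auc=fold_auc, fold_accuracy=fold_acc, k=k, seed=seed)
        )
    return reports


class SeparabilityAnalysis:
    """Separability model over a labelled feature table.

    Parameters
    ----------
    features : pandas.DataFrame
        Must carry the index columns (Z1/Z14/fmid or the canonical
        z1_ohm/z14_ohm/fmid_hz names) and either a ``gland`` column or
        explicit ``labels``.
    """

    _ALIASES = {"z1_ohm": "Z1", "z14_ohm": "Z14", "fmid_hz": "fmid"}

    def __init__(self, features: pd.DataFrame, labels=None):
        df = pd.DataFrame(features).rename(columns=self._ALIASES)
        if labels is None:
            if "gland" not in df.columns:
                raise ValueError("provide labels or a 'gland' column")
            labels = df["gland"].to_numpy()
        self.labels = np.asarray(labels)
        self.index_names = [c for c in ("Z1", "Z14", "fmid") if c in df.columns]
        if not self.index_names:
            raise ValueError("no spectrum-index columns found")
        self.features = df[self.index_names].reset_index(drop=True)

    def fit(self, k: int = 20, seed: int = 0, classifiers: bool = True) -> "SeparabilityResults":
        is_t = self.labels == ("thyroid" if self.labels.dtype.kind in "UO" else 1)
        rocs = [
            best_direction_auc(
                self.features[name][is_t].to_numpy(),
                self.features[name][~is_t].to_numpy(),
                index_name=name,
            )
            for name in self.index_names
        ]
        cv = (
            cross_validate_classifiers(self.features, self.labels, k=k, seed=seed)
            if classifiers
            else []
        )
        return SeparabilityResults(roc=rocs, cv=cv)


@dataclass
class SeparabilityResults:
    roc: list[ROCResult]
    cv: list[CVReport]

    @property
    def roc_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"index": r.index_name, "direction": r.direction, "auc": r.auc}
                for r in self.roc
            ]
        )

    @property
    def cv_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "classifier": r.classifier,
                    "mean_auc": r.mean_auc,
                    "mean_accuracy": r.mean_accuracy,
                    "k": r.k,
                }
                for r in self.cv
            ]
        )

    def to_dict(self) -> dict:
        return {
            "roc": self.roc_table.to_dict(orient="records"),
            "cv": self.cv_table.to_dict(orient="records"),
        }

    def summary(self) -> str:
        lines = ["Separability summary", "=" * 20, "Per-index manual ROC:"]
        for r in self.roc:
            lines.append(f"  {r.index_name:>5s}  direction {r.direction}  AUC {r.auc:.3f}")
        if self.cv:
            lines.append("20-fold cross-validated classifiers (Z1, Z14, fmid):")
            for c in self.cv:
                lines.append(
                    f"  {c.classifier}: mean AUC {c.mean_auc:.3f}, "
                    f"mean accuracy {c.mean_accuracy:.3f}"
                )
        return "\n".join(lines)
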