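"""One-vs-one linear SVM and repeated hold-out evaluation.

The classifier is the LIBLINEAR-style L2-regularized squared-hinge linear
SVM (sklearn ``LinearSVC``), one binary model per class pair (6 for the
four classes), with majority voting.  Per-class continuous scores — needed
for one-vs-rest ROC curves — are the sums of signed pairwise decision
values involving each class; voting ties break toward the larger summed
score, then canonical class order.

Evaluation follows a repeated stratified hold-out: each repeat splits
every class's windows 80:20 at random, fits the scaler and SVM on the
training part only, and measures accuracy, per-class recall, F1 and
one-vs-rest AUC on the held-out part; metrics are averaged over repeats
(100 by default) and confusion counts summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .channels import CLASSES
from .errors import ParameterError, ValidationError
from .features import FeatureMatrix

__all__ = [
    "SvmConfig",
    "OvoLinearSvm",
    "EvalReport",
    "train_svm",
    "predict",
    "roc_auc_one_vs_rest",
    "holdout_evaluate",
    "f1_from_confusion",
]


@dataclass(frozen=True)
class SvmConfig:
    """Linear SVM settings: penalty C, feature z-scoring, seed."""

    penalty: float = 1.0
    scale_features: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.penalty <= 0:
            raise ParameterError("penalty C must be positive")


class OvoLinearSvm:
    """One-vs-one ensemble of binary linear SVMs with a fitted scaler."""

    def __init__(self, config: SvmConfig):
        self.config = config
        self.classes_: list[str] = []
        self.scaler_: StandardScaler | None = None
        self.models_: dict[tuple[str, str], LinearSVC] = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OvoLinearSvm":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        present = [c for c in CLASSES if c in set(y)]
        present += sorted(set(y) - set(CLASSES))
        if len(present) < 2:
            raise ValidationError("training data must contain >= 2 classes")
        self.classes_ = present
        if self.config.scale_features:
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        self.models_ = {}
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                mask = (y == a) | (y == b)
                svc = LinearSVC(
                    C=self.config.penalty,
                    loss="squared_hinge",
                    penalty="l2",
                    random_state=self.config.seed,
                )
                # binary target: 1 for class b, so decision > 0 votes b
                svc.fit(X[mask], (y[mask] == b).astype(int))
                self.models_[(a, b)] = svc
        return self

    def decision_scores(self, X: np.ndarray) -> pd.DataFrame:
        """Summed signed pairwise confidences per class.

        Each pairwise decision value is squashed through tanh before
        summing, so a pairwise model that does not involve a sample's
        true class cannot dominate the sample's score with an arbitrarily
        large extrapolated margin — the standard guard when one-vs-one
        decision values are aggregated for ROC scoring.
        """
        X = np.asarray(X, dtype=float)
        n_dim = next(iter(self.models_.values())).coef_.shape[1]
        if X.ndim != 2 or X.shape[1] != n_dim:
            raise ValidationError(
                f"feature dimension {X.shape} does not match training ({n_dim})"
            )
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        scores = pd.DataFrame(0.0, index=range(len(X)), columns=self.classes_)
        self._votes = pd.DataFrame(0, index=range(len(X)), columns=self.classes_)
        for (a, b), svc in self.models_.items():
            d = np.tanh(svc.decision_function(X))
            scores[b] += d
            scores[a] -= d
            self._votes[b] += (d > 0).astype(int)
            self._votes[a] += (d <= 0).astype(int)
        return scores

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
        """Majority-vote labels plus per-class scores.

        Ties in the vote break toward the larger summed decision value,
        then toward canonical class order.
        """
        scores = self.decision_scores(X)
        votes = self._votes
        labels = []
        for i in range(len(scores)):
            v = votes.iloc[i]
            tied = [c for c in self.classes_ if v[c] == v.max()]
            if len(tied) > 1:
                s = scores.iloc[i]
                best = max(s[c] for c in tied)
                tied = [c for c in tied if s[c] == best]
            labels.append(tied[0])
        return np.array(labels), scores


def train_svm(features, labels, config: SvmConfig | None = None) -> OvoLinearSvm:
    """Fit the one-vs-one linear SVM (scaler + 6 pairwise classifiers)."""
    config = config or SvmConfig()
    if isinstance(features, FeatureMatrix):
        labels = features.labels
        features = features.values.to_numpy()
    return OvoLinearSvm(config).fit(np.asarray(features), np.asarray(labels))


def predict(model: OvoLinearSvm, features) -> tuple[np.ndarray, pd.DataFrame]:
    if isinstance(features, FeatureMatrix):
        features = features.values.to_numpy()
    return model.predict(np.asarray(features))


def roc_auc_one_vs_rest(scores: pd.DataFrame, labels: np.ndarray) -> dict:
    """Per-class ROC points and trapezoidal AUC, current class positive.

    A class with no positive or no negative examples gets ``roc=None,
    auc=nan`` (undefined).
    """
    labels = np.asarray(labels)
    out = {}
    for cls in scores.columns:
        y = (labels == cls).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            out[cls] = {"roc": None, "auc": float("nan")}
            continue
        fpr, tpr, _ = roc_curve(y, scores[cls].to_numpy())
        out[cls] = {
            "roc": np.column_stack([fpr, tpr]),
            "auc": float(np.trapezoid(tpr, fpr)),
        }
    return out


def f1_from_confusion(confusion: np.ndarray, class_index: int) -> float:
    """One-vs-rest F1 of one class from a confusion-count matrix."""
    tp = confusion[class_index, class_index]
    fn = confusion[class_index].sum() - tp
    fp = confusion[:, class_index].sum() - tp
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else float("nan")


@dataclass
class EvalReport:
    """Aggregated repeated hold-out results (class order NC, LF, TR, SE)."""

    classes: tuple[str, ...]
    confusion: np.ndarray  # summed counts over repeats, rows = true class
    per_class_accuracy: dict[str, float]  # mean per-class recall
    overall_accuracy_mean: float
    overall_accuracy_sd: float
    f1: dict[str, float]  # mean per-repeat one-vs-rest F1
    auc: dict[str, float]  # mean per-repeat one-vs-rest AUC
    roc: dict[str, np.ndarray]  # pooled-score ROC points per class
    repeats: int
    split: float
    skipped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": {k: round(v, 10) for k, v in
                                   self.per_class_accuracy.items()},
            "overall_accuracy_mean": round(self.overall_accuracy_mean, 10),
            "overall_accuracy_sd": round(self.overall_accuracy_sd, 10),
            "f1": {k: round(v, 10) for k, v in self.f1.items()},
            "auc": {k: round(v, 10) for k, v in self.auc.items()},
            "roc": {k: np.round(v, 10).tolist() for k, v in self.roc.items()},
            "repeats": self.repeats,
            "split": self.split,
            "skipped": self.skipped,
        }


def holdout_evaluate(
    features: FeatureMatrix,
    config: SvmConfig | None = None,
    repeats: int = 100,
    train_fraction: float = 0.8,
    trial_level: bool = False,
) -> EvalReport:
    """Repeated stratified hold-out evaluation.

    Splitting is at window level by default, mirroring per-class random
    division of the feature set (windows of one trial can then appear in
    both halves — an optimistic convention; set ``trial_level=True`` to
    split whole recordings instead).
    """
    config = config or SvmConfig()
    if not (0 < train_fraction < 1):
        raise ParameterError("train_fraction must be in (0, 1)")
    X = features.values.to_numpy()
    y = features.labels
    present = [c for c in CLASSES if c in set(y)]
    for cls in present:
        if (y == cls).sum() < 5:
            raise ValidationError(
                f"class {cls} has fewer than 5 rows; hold-out split undefined"
            )
    groups = np.array([rid for rid, _ in features.window_index]) if trial_level else None
    rng = np.random.default_rng(config.seed)
    k = len(present)
    confusion = np.zeros((k, k), dtype=int)
    acc, recalls, f1s, aucs = [], [], [], []
    pooled_scores, pooled_labels = [], []
    cls_pos = {c: i for i, c in enumerate(present)}
    for _ in range(repeats):
        train_idx, test_idx = _stratified_split(y, present, train_fraction, rng, groups)
        model = OvoLinearSvm(config).fit(X[train_idx], y[train_idx])
        pred, scores = model.predict(X[test_idx])
        yt = y[test_idx]
        cm = np.zeros((k, k), dtype=int)
        for t, p in zip(yt, pred):
            cm[cls_pos[t], cls_pos[p]] += 1
        confusion += cm
        acc.append(np.trace(cm) / cm.sum())
        recalls.append([cm[i, i] / cm[i].sum() if cm[i].sum() else np.nan
                        for i in range(k)])
        f1s.append([f1_from_confusion(cm, i) for i in range(k)])
        ra = roc_auc_one_vs_rest(scores, yt)
        aucs.append([ra[c]["auc"] for c in present])
        pooled_scores.append(scores)
        pooled_labels.append(yt)
    pooled = roc_auc_one_vs_rest(
        pd.concat(pooled_scores, ignore_index=True), np.concatenate(pooled_labels)
    )
    return EvalReport(
        classes=tuple(present),
        confusion=confusion,
        per_class_accuracy=dict(zip(present, np.nanmean(recalls, axis=0))),
        overall_accuracy_mean=float(np.mean(acc)),
        overall_accuracy_sd=float(np.std(acc)),
        f1=dict(zip(present, np.nanmean(f1s, axis=0))),
        auc=dict(zip(present, np.nanmean(aucs, axis=0))),
        roc={c: pooled[c]["roc"] for c in present if pooled[c]["roc"] is not None},
        repeats=repeats,
        split=train_fraction,
    )


def _stratified_split(y, present, train_fraction, rng, groups=None):
    """Per-class random split; with ``groups`` whole trials are assigned."""
    train, test = [], []
    for cls in present:
        idx = np.flatnonzero(y == cls)
        if groups is None:
            idx = idx[rng.permutation(len(idx))]
            n_train = int(train_fraction * len(idx))
            n_train = min(max(n_train, 1), len(idx) - 1)
            train.extend(idx[:n_train])
            test.extend(idx[n_train:])
        else:
            gids = np.unique(groups[idx])
            gids = gids[rng.permutation(len(gids))]
            n_train = min(max(int(train_fraction * len(gids)), 1), len(gids) - 1)
            keep = set(gids[:n_train])
            for i in idx:
                (train if groups[i] in keep else test).append(i)
    return np.array(train), np.array(test)
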