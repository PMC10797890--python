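"""Fisher-score + linear-SVM fusion classifier with LOOCV / k-fold evaluation.

Pipeline reproduced here: min-max normalization to [0, 1], Fisher-score
ranking with the top 100 features kept, a linear soft-margin SVM, the ten
largest-|weight| features retained, margin parameter C tuned in an inner
cross-validation loop, per-modality top-10 sets fused by union and re-ranked,
and evaluation by leave-one-out or stratified k-fold cross-validation with
accuracy/sensitivity/specificity/F1/ROC-AUC/PR-AUC.

Two preprocessing scopes are provided.  ``global`` normalizes and selects
features on the full data set before cross-validation (the classical but
leakage-prone protocol); ``train_fold`` redoes normalization, selection and
tuning inside every training fold.  Reports are flagged with the scope used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import average_precision_score, roc_curve, auc as trapezoid_auc
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import NeurofuseError

DEFAULT_C_GRID = tuple(2.0**k for k in range(-5, 6))


# ---------------------------------------------------------------------------
# normalization


class FoldMinMaxScaler(BaseEstimator, TransformerMixin):
    """Per-feature (x - min) / (max - min) with training-fold statistics.

    Constant features map to 0; transformed values are clipped to [0, 1] so
    test subjects never leave the training range.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise NeurofuseError("min-max normalization requires finite values")
        self.min_ = X.min(axis=0)
        self.range_ = X.max(axis=0) - self.min_
        return self

    def transform(self, X):
        check_is_fitted(self, "min_")
        X = np.asarray(X, dtype=float)
        rng = np.where(self.range_ > 0, self.range_, 1.0)
        out = (X - self.min_) / rng
        out[:, self.range_ == 0] = 0.0
        return np.clip(out, 0.0, 1.0)


def minmax_normalize(X, scope: str = "global", train_idx=None):
    """Normalize features to [0, 1].

    ``scope='global'`` uses the whole matrix; ``scope='train_fold'`` fits the
    min/max on ``train_idx`` rows only and clips the rest into [0, 1].
    """
    X = np.asarray(X, dtype=float)
    scaler = FoldMinMaxScaler()
    if scope == "global":
        return scaler.fit_transform(X)
    if scope == "train_fold":
        if train_idx is None:
            raise NeurofuseError("train_fold scope requires train_idx")
        scaler.fit(X[train_idx])
        return scaler.transform(X)
    raise NeurofuseError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# Fisher score selection


def fisher_score(X, y, variance_floor: float = 1e-12):
    """Two-class Fisher score per feature.

    F_j = [n1 (mu1-mu)^2 + n2 (mu2-mu)^2] / [n1 s1^2 + n2 s2^2] with
    population (ddof=0) within-class variances; the denominator is floored at
    ``variance_floor`` so separable features get a large finite score.
    Returns (scores, order) where ``order`` ranks features by descending
    score, ties broken by ascending feature index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise NeurofuseError("Fisher score requires exactly two classes")
    x1 = X[y == classes[0]]
    x2 = X[y == classes[1]]
    if len(x1) < 2 or len(x2) < 2:
        raise NeurofuseError("each class needs n >= 2")
    n1, n2 = len(x1), len(x2)
    mu = X.mean(axis=0)
    num = n1 * (x1.mean(axis=0) - mu) ** 2 + n2 * (x2.mean(axis=0) - mu) ** 2
    den = n1 * x1.var(axis=0, ddof=0) + n2 * x2.var(axis=0, ddof=0)
    scores = num / np.maximum(den, variance_floor)
    order = np.lexsort((np.arange(X.shape[1]), -scores))
    return scores, order


def select_top_k(order, k: int = 100):
    """First k indices of a deterministic ranking."""
    order = np.asarray(order)
    if k > order.size:
        raise NeurofuseError(f"k={k} exceeds {order.size} features")
    return order[:k]


class FisherScoreSelector(SelectorMixin, BaseEstimator):
    """sklearn feature selector keeping the k highest Fisher scores."""

    def __init__(self, k: int = 100):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.scores_, order = fisher_score(X, y)
        self.selected_ = select_top_k(order, min(self.k, X.shape[1]))
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "selected_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask


# ---------------------------------------------------------------------------
# linear SVM


@dataclass
class LinearModel:
    """Trained linear decision function sign(w.x + b)."""

    weights: np.ndarray
    bias: float
    C: float
    feature_idx: np.ndarray
    classes: tuple = (-1, 1)

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes[1], self.classes[0])


def _encode_labels(y, positive_label=None):
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise NeurofuseError("binary labels required")
    if positive_label is None:
        positive_label = classes[1]
    if positive_label not in classes:
        raise NeurofuseError(f"positive label {positive_label!r} not in labels")
    negative_label = classes[classes != positive_label][0]
    yv = np.where(y == positive_label, 1, -1)
    return yv, negative_label, positive_label


def train_linear_svm(X, y, C: float = 1.0, feature_idx=None, positive_label=None) -> LinearModel:
    """Soft-margin linear SVM (libsvm); returns explicit (w, b)."""
    if C <= 0:
        raise NeurofuseError("C must be positive")
    X = np.asarray(X, dtype=float)
    yv, neg, pos = _encode_labels(y, positive_label)
    if feature_idx is not None:
        X = X[:, feature_idx]
    else:
        feature_idx = np.arange(X.shape[1])
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, yv)
    return LinearModel(
        weights=svc.coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        feature_idx=np.asarray(feature_idx),
        classes=(neg, pos),
    )


def top_contributors(model: LinearModel, k: int = 10):
    """k features with largest |weight|; ties broken by ascending feature id.

    Indices are reported in the coordinate system of ``model.feature_idx``.
    """
    w = np.abs(model.weights)
    if k > w.size:
        raise NeurofuseError(f"k={k} exceeds {w.size} model features")
    order = np.lexsort((model.feature_idx, -w))
    return model.feature_idx[order[:k]]


# ---------------------------------------------------------------------------
# cross-validation schemes


@dataclass
class CVScheme:
    """LOOCV or (stratified, shuffled) k-fold."""

    kind: str = "loocv"  # "loocv" | "kfold"
    k: int = 10
    seed: int = 0

    def folds(self, y) -> list[np.ndarray]:
        """Return a list of test-index arrays partitioning the subjects."""
        y = np.asarray(y)
        n = len(y)
        if self.kind == "loocv":
            return [np.array([i]) for i in range(n)]
        if self.kind != "kfold":
            raise NeurofuseError(f"unknown CV kind {self.kind!r}")
        rng = np.random.default_rng(self.seed)
        test_sets: list[list[int]] = [[] for _ in range(self.k)]
        # stratified round-robin over shuffled per-class indices
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                test_sets[j % self.k].append(int(i))
        return [np.sort(np.array(s, dtype=int)) for s in test_sets if s]


def tune_C(X, y, grid=DEFAULT_C_GRID, scheme: CVScheme | None = None, positive_label=None):
    """Inner-loop CV accuracy per C; best = highest accuracy, ties -> smallest C."""
    grid = sorted(grid)
    if not grid:
        raise NeurofuseError("empty C grid")
    scheme = scheme or CVScheme("loocv")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    scores: dict[float, float] = {}
    for C in grid:
        correct = total = 0
        for test_idx in scheme.folds(y):
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            if np.unique(y[train_idx]).size < 2:
                continue
            model = train_linear_svm(X[train_idx], y[train_idx], C=C,
                                     positive_label=positive_label)
            correct += int((model.predict(X[test_idx]) == y[test_idx]).sum())
            total += len(test_idx)
        if total == 0:
            raise NeurofuseError("degenerate folds: no fold had both classes in training")
        scores[C] = correct / total
    best = max(scores, key=lambda c: (scores[c], -c))
    return best, scores


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    roc_auc: float
    pr_auc: float
    roc_curve: tuple
    pr_curve: tuple
    operating_point: tuple
    positive_label: object
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "operating_point": list(self.operating_point),
            "positive_label": str(self.positive_label),
            **({"metadata": self.metadata} if self.metadata else {}),
        }


def classification_metrics(y_true, y_pred, decision_values=None, positive_label=None,
                           metadata: dict | None = None) -> MetricsReport:
    """Confusion-matrix metrics plus ROC/PR curves from decision values.

    ROC AUC is the trapezoidal area; PR-AUC is the step-wise (average
    precision) area; the operating point is the ROC point maximizing
    Youden's J = TPR - FPR.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise NeurofuseError("length mismatch")
    yt, _, pos = _encode_labels(y_true, positive_label)
    yp = np.where(y_pred == pos, 1, -1)
    tp = int(((yt == 1) & (yp == 1)).sum())
    fp = int(((yt == -1) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == -1)).sum())
    tn = int(((yt == -1) & (yp == -1)).sum())
    n = tp + fp + fn + tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0

    if decision_values is None:
        decision_values = yp.astype(float)
    fpr, tpr, _ = roc_curve(yt, decision_values)
    roc_auc = float(trapezoid_auc(fpr, tpr))
    pr_auc = float(average_precision_score(yt, decision_values))
    from sklearn.metrics import precision_recall_curve

    pcurve, rcurve, _ = precision_recall_curve(yt, decision_values)
    j = tpr - fpr
    best = int(np.argmax(j))
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / n,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        roc_auc=roc_auc,
        pr_auc=pr_auc,
        roc_curve=(fpr, tpr),
        pr_curve=(pcurve, rcurve),
        operating_point=(float(fpr[best]), float(tpr[best])),
        positive_label=pos,
        metadata=metadata or {},
    )


def confusion_from_rates(N: int, precision: float, recall: float,
                         n_positive: int | None = None, decimals: int = 2):
    """Integer confusion matrices consistent with printed precision/recall.

    Enumerates (TP, FP, FN, TN) with TP+FN = n_positive (or every feasible
    n_positive) whose precision and recall, rounded to ``decimals`` decimal
    places of percent, equal the supplied rates.  Returns
    ``(matches, nearest)``: exact matches, and when there are none, the
    candidates minimizing squared error in (precision, recall).
    """
    if not (0 < precision <= 1 and 0 < recall <= 1):
        raise NeurofuseError("rates must be in (0, 1]")
    pos_range = [n_positive] if n_positive is not None else list(range(1, N))
    matches, candidates = [], []
    for npos in pos_range:
        for tp in range(0, npos + 1):
            fn = npos - tp
            for fp in range(0, N - npos + 1):
                tn = N - npos - fp
                if tp + fp == 0:
                    continue
                prec = tp / (tp + fp)
                rec = tp / npos
                entry = {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
                         "precision": prec, "recall": rec,
                         "accuracy": (tp + tn) / N}
                err = (prec - precision) ** 2 + (rec - recall) ** 2
                candidates.append((err, entry))
                if (round(prec * 100, decimals) == round(precision * 100, decimals)
                        and round(rec * 100, decimals) == round(recall * 100, decimals)):
                    matches.append(entry)
    if matches:
        return matches, []
    candidates.sort(key=lambda t: t[0])
    best_err = candidates[0][0]
    nearest = [e for err, e in candidates if err <= best_err + 1e-12]
    return [], nearest


# ---------------------------------------------------------------------------
# the full estimator and evaluation


class OmicsFusionClassifier(BaseEstimator, ClassifierMixin):
    """Min-max -> Fisher top-k -> linear SVM -> top-m re-rank -> tuned SVM.

    A fold-honest sklearn estimator: everything (scaling, selection, tuning)
    is fitted on the training data passed to :meth:`fit`.

    Parameters
    ----------
    top_k : int
        Features kept by Fisher score (study protocol: 100).
    final_k : int
        Features kept by |SVM weight| re-ranking (study protocol: 10).
    C : float
        Margin parameter used when ``tune_grid`` is None.
    tune_grid : sequence of float or None
        When given, C is chosen by inner LOOCV accuracy on the final features.
    positive_label : hashable or None
        Label treated as the positive class (default: second sorted label).
    """

    def __init__(self, top_k: int = 100, final_k: int = 10, C: float = 1.0,
                 tune_grid=None, positive_label=None):
        self.top_k = top_k
        self.final_k = final_k
        self.C = C
        self.tune_grid = tune_grid
        self.positive_label = positive_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.scaler_ = FoldMinMaxScaler().fit(X)
        Xn = self.scaler_.transform(X)
        k = min(self.top_k, X.shape[1])
        _, order = fisher_score(Xn, y)
        selected = select_top_k(order, k)
        ranking_model = train_linear_svm(Xn, y, C=self.C, feature_idx=selected,
                                         positive_label=self.positive_label)
        self.final_features_ = top_contributors(ranking_model, min(self.final_k, k))
        if self.tune_grid:
            self.C_, self.tuning_scores_ = tune_C(
                Xn[:, self.final_features_], y, grid=self.tune_grid,
                positive_label=self.positive_label)
        else:
            self.C_ = self.C
            self.tuning_scores_ = {}
        self.model_ = train_linear_svm(Xn, y, C=self.C_,
                                       feature_idx=self.final_features_,
                                       positive_label=self.positive_label)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        Xn = self.scaler_.transform(np.asarray(X, dtype=float))
        return self.model_.decision_function(Xn[:, self.model_.feature_idx])

    def predict(self, X):
        check_is_fitted(self, "model_")
        d = self.decision_function(X)
        neg, pos = self.model_.classes
        return np.where(d >= 0, pos, neg)


def fuse_modalities(per_modality_top: list[np.ndarray], X, y, C: float = 1.0,
                    final_k: int = 10, positive_label=None):
    """Union the per-modality top features, retrain, re-rank to ``final_k``.

    Returns (candidate ids, final ids).  ``X`` must be in the same (already
    normalized) coordinate system the per-modality indices refer to.
    """
    seen: dict[int, None] = {}
    for lst in per_modality_top:
        for i in np.asarray(lst).tolist():
            seen.setdefault(int(i), None)
    candidates = np.array(list(seen), dtype=int)
    if candidates.size == 0:
        raise NeurofuseError("empty fused candidate set")
    model = train_linear_svm(X, y, C=C, feature_idx=candidates,
                             positive_label=positive_label)
    final = top_contributors(model, min(final_k, candidates.size))
    return candidates, final


def fused_cv_evaluate(X, y, modality_indices: list[np.ndarray],
                      config: "PipelineConfig | None" = None,
                      scheme: "CVScheme | None" = None) -> dict:
    """Cross-validated evaluation of the multi-modality fusion pipeline.

    Inside every training fold: min-max scaling, Fisher top-k and |weight|
    re-ranking per modality, union of the per-modality top sets, retraining on
    the union and a final re-rank to ``final_k`` features (``scope='global'``
    instead performs all of that once on the full data set, the study
    protocol).  Returns the same structure as :func:`cv_evaluate`.
    """
    config = config or PipelineConfig()
    scheme = scheme or CVScheme("loocv")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    preds = np.empty(n, dtype=object)
    decvals = np.full(n, np.nan)
    skipped: list[int] = []

    def _fuse_on(train_idx):
        tops = []
        for idx in modality_indices:
            Xn = minmax_normalize(X[:, idx], scope="train_fold",
                                  train_idx=train_idx)
            _, order = fisher_score(Xn[train_idx], y[train_idx])
            sel = select_top_k(order, min(config.top_k, len(idx)))
            m = train_linear_svm(Xn[train_idx], y[train_idx], C=config.C,
                                 feature_idx=sel,
                                 positive_label=config.positive_label)
            tops.append(idx[top_contributors(m, min(config.final_k, sel.size))])
        Xn = minmax_normalize(X, scope="train_fold", train_idx=train_idx)
        _, final = fuse_modalities(tops, Xn[train_idx], y[train_idx],
                                   C=config.C, final_k=config.final_k,
                                   positive_label=config.positive_label)
        if config.tune_grid:
            best_C, _ = tune_C(Xn[train_idx][:, final], y[train_idx],
                               grid=config.tune_grid,
                               positive_label=config.positive_label)
        else:
            best_C = config.C
        model = train_linear_svm(Xn[train_idx], y[train_idx], C=best_C,
                                 feature_idx=final,
                                 positive_label=config.positive_label)
        return Xn, model, final

    if config.scope == "global":
        all_idx = np.arange(n)
        Xn, _, final = _fuse_on(all_idx)
        sub_config = PipelineConfig(scope="global", top_k=len(final),
                                    final_k=len(final), C=config.C,
                                    tune_grid=config.tune_grid,
                                    positive_label=config.positive_label)
        out = cv_evaluate(X[:, final], y, sub_config, scheme)
        out["report"].metadata["fused_features"] = [int(i) for i in final]
        return out

    for test_idx in scheme.folds(y):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if np.unique(y[train_idx]).size < 2:
            skipped.extend(test_idx.tolist())
            continue
        Xn, model, final = _fuse_on(train_idx)
        preds[test_idx] = model.predict(Xn[test_idx][:, final])
        decvals[test_idx] = model.decision_function(Xn[test_idx][:, final])
    ok = np.array([i for i in range(n) if i not in skipped])
    report = classification_metrics(
        y[ok], preds[ok].astype(y.dtype), decvals[ok],
        positive_label=config.positive_label,
        metadata={"scope": config.scope, "cv": scheme.kind, "fused": True,
                  "skipped_folds": len(skipped)})
    return {"predictions": preds, "decision_values": decvals,
            "skipped": skipped, "report": report}


@dataclass
class PipelineConfig:
    """What happens inside (or before) each CV fold."""

    scope: str = "global"  # "global" (study protocol, leaky) | "train_fold"
    top_k: int = 100
    final_k: int = 10
    C: float = 1.0
    tune_grid: tuple | None = DEFAULT_C_GRID
    positive_label: object = None


def cv_evaluate(X, y, config: PipelineConfig | None = None,
                scheme: CVScheme | None = None) -> dict:
    """Cross-validated evaluation of the fusion pipeline.

    With ``scope='global'`` normalization, Fisher selection, weight re-ranking
    and C tuning happen once on the full data set (the study protocol; this
    leaks test information into selection and the report is flagged
    accordingly).  With ``scope='train_fold'`` the whole pipeline is refitted
    inside every training fold.

    Returns a dict with pooled predictions, decision values, the fold map and
    a :class:`MetricsReport`.
    """
    config = config or PipelineConfig()
    scheme = scheme or CVScheme("loocv")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) < 4:
        raise NeurofuseError("need at least 4 subjects")
    n = len(y)
    preds = np.empty(n, dtype=object)
    decvals = np.full(n, np.nan)
    skipped: list[int] = []

    if config.scope == "global":
        Xn = minmax_normalize(X, scope="global")
        _, order = fisher_score(Xn, y)
        selected = select_top_k(order, min(config.top_k, X.shape[1]))
        ranking_model = train_linear_svm(Xn, y, C=config.C, feature_idx=selected,
                                         positive_label=config.positive_label)
        final = top_contributors(ranking_model, min(config.final_k, selected.size))
        if config.tune_grid:
            best_C, _ = tune_C(Xn[:, final], y, grid=config.tune_grid,
                               positive_label=config.positive_label)
        else:
            best_C = config.C
        for test_idx in scheme.folds(y):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            if np.unique(y[train_idx]).size < 2:
                skipped.extend(test_idx.tolist())
                continue
            model = train_linear_svm(Xn[train_idx], y[train_idx], C=best_C,
                                     feature_idx=final,
                                     positive_label=config.positive_label)
            preds[test_idx] = model.predict(Xn[test_idx][:, final])
            decvals[test_idx] = model.decision_function(Xn[test_idx][:, final])
        extras = {"selected_features": final, "C": best_C}
    elif config.scope == "train_fold":
        est = OmicsFusionClassifier(top_k=config.top_k, final_k=config.final_k,
                                    C=config.C, tune_grid=config.tune_grid,
                                    positive_label=config.positive_label)
        for test_idx in scheme.folds(y):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            if np.unique(y[train_idx]).size < 2:
                skipped.extend(test_idx.tolist())
                continue
            est.fit(X[train_idx], y[train_idx])
            preds[test_idx] = est.predict(X[test_idx])
            decvals[test_idx] = est.decision_function(X[test_idx])
        extras = {}
    else:
        raise NeurofuseError(f"unknown scope {config.scope!r}")

    ok = np.array([i for i in range(n) if i not in skipped])
    report = classification_metrics(
        y[ok], preds[ok].astype(y.dtype), decvals[ok],
        positive_label=config.positive_label,
        metadata={"scope": config.scope, "cv": scheme.kind,
                  "k": (len(y) if scheme.kind == "loocv" else scheme.k),
                  "skipped_folds": len(skipped), **{k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in extras.items()}},
    )
    return {"predictions": preds, "decision_values": decvals,
            "skipped": skipped, "report": report}
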