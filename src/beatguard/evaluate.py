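"""Classification metrics, ablation runner, effect sizes and exact CIs.

Metrics follow the standard confusion-matrix definitions (accuracy,
precision, recall, F1 as the harmonic mean of precision and recall);
multiclass discrimination is summarized as macro one-vs-rest ROC AUC.
Exact binomial confidence intervals are Clopper–Pearson, via Beta
quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm
from sklearn.model_selection import train_test_split

from .features import FEATURE_GROUPS, FEATURE_NAMES
from .model import Hyperparams, LabeledFeatures, predict_proba, train

#: Cumulative ablation configurations over the four feature groups.
ABLATION_STAGES = {
    "A1": ("statistical",),
    "A2": ("statistical", "fiducial"),
    "A3": ("statistical", "fiducial", "wavelet"),
    "A4": ("statistical", "fiducial", "wavelet", "hrv_nonlinear"),
}


@dataclass
class MetricsReport:
    classes: list[str]
    counts: dict[str, dict[str, int]]        # per-class TP/TN/FP/FN
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_f1: float
    auc: dict[str, float | None] = field(default_factory=dict)
    macro_auc: float | None = None
    confusion: np.ndarray | None = None      # row-normalized

    def as_dict(self) -> dict:
        return {
            "classes": self.classes,
            "counts": self.counts,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "macro_f1": self.macro_f1,
            "auc": self.auc,
            "macro_auc": self.macro_auc,
            "confusion": None if self.confusion is None
            else self.confusion.tolist(),
        }


def classification_metrics(y_true, y_pred, probs: np.ndarray | None = None,
                           classes: list[str] | None = None) -> MetricsReport:
    """Per-class and macro metrics from labels and optional probabilities.

    ``probs`` columns must align with ``classes`` (sorted unique labels by
    default).  AUC for a class absent from ``y_true`` is masked (None).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    classes = classes or sorted(set(y_true.tolist()) | set(y_pred.tolist()))

    counts: dict[str, dict[str, int]] = {}
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    f1: dict[str, float] = {}
    for c in classes:
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        tn = int(np.sum((y_pred != c) & (y_true != c)))
        counts[c] = {"tp": tp, "tn": tn, "fp": fp, "fn": fn}
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precision[c], recall[c] = p, r
        f1[c] = 2 * p * r / (p + r) if p + r else 0.0

    accuracy = float(np.mean(y_true == y_pred))
    macro_f1 = float(np.mean([f1[c] for c in classes]))

    auc: dict[str, float | None] = {}
    macro_auc = None
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        present = []
        for j, c in enumerate(classes):
            y_bin = (y_true == c).astype(int)
            if 0 < y_bin.sum() < y_bin.size:
                auc[c] = float(skm.roc_auc_score(y_bin, probs[:, j]))
                present.append(auc[c])
            else:
                auc[c] = None
        macro_auc = float(np.mean(present)) if present else None

    cm = skm.confusion_matrix(y_true, y_pred, labels=classes).astype(float)
    row = cm.sum(axis=1, keepdims=True)
    cm = np.divide(cm, row, out=np.zeros_like(cm), where=row > 0)
    return MetricsReport(
        classes=list(classes), counts=counts, accuracy=accuracy,
        precision=precision, recall=recall, f1=f1, macro_f1=macro_f1,
        auc=auc, macro_auc=macro_auc, confusion=cm,
    )


def ablation_run(table: pd.DataFrame, hp: Hyperparams | None = None,
                 test_size: float = 0.3, seed: int = 0,
                 stages: dict[str, tuple[str, ...]] | None = None
                 ) -> dict[str, MetricsReport]:
    """Train/evaluate the cumulative feature-group configurations.

    All stages share the same hyperparameters and the same stratified
    train/test split, so differences are attributable to the feature set.
    """
    stages = stages or ABLATION_STAGES
    y = table["label"].astype(str).to_numpy()
    idx = np.arange(len(table))
    tr, te = train_test_split(idx, test_size=test_size, random_state=seed,
                              stratify=y)
    out: dict[str, MetricsReport] = {}
    for stage, groups in stages.items():
        names = [n for g in groups for n in FEATURE_GROUPS[g]]
        X = table[names].to_numpy(dtype=float)
        feats = LabeledFeatures(X[tr], list(y[tr]), names,
                                provenance=f"ablation-{stage}")
        bundle = train(feats, hp)
        probs = predict_proba(bundle, X[te])
        pred = [bundle.classes[i] for i in np.argmax(probs, axis=1)]
        out[stage] = classification_metrics(
            y[te], pred, probs, classes=bundle.classes)
    return out


def effect_sizes(baseline: float, new: float
                 ) -> tuple[float, float | None]:
    """Absolute Δ (new − baseline) and relative % change (2-dp convention).

    A zero baseline masks the percent change rather than fabricating one.
    """
    delta = new - baseline
    if baseline == 0:
        return delta, None
    return delta, 100.0 * delta / baseline


@dataclass(frozen=True)
class CIResult:
    successes: int
    trials: int
    level: float
    lower: float
    upper: float

    @property
    def proportion(self) -> float:
        return self.successes / self.trials


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> CIResult:
    """Clopper–Pearson exact interval via Beta quantiles."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n and n >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(
        stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return CIResult(successes=k, trials=n, level=level,
                    lower=lower, upper=upper)
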