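"""Classifier evaluation: confusion counts, threshold metrics, ROC/PR areas,
per-fold validation runs and the scrambled-label control.

Conventions for degenerate cases: precision is 0 when no positive predictions
are made; recall is 0 when TP = 0 with FN > 0 and NaN when there are no
actual positives; AUROC/AUPR are NaN when only one class is present.  ROC
ties are grouped at a single threshold and integrated with the trapezoid
rule; the PR area uses the step integral (no interpolation between points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ModelInput, SplitPlan, scramble_labels, split
from .errors import InputError
from .models import ArchitectureSpec, NeuralClassifier, TrainConfig, TrainingResult

__all__ = [
    "ConfusionCounts", "MetricsReport",
    "confusion", "metrics", "evaluate_split", "scrambled_control",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Threshold metrics at one cutoff plus threshold-free curve areas."""

    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    fpr: float
    specificity: float
    auroc: float
    aupr: float
    roc_curve: pd.DataFrame  # columns: threshold, fpr, tpr
    pr_curve: pd.DataFrame   # columns: threshold, recall, precision

    def to_dict(self) -> dict:
        return {
            "TP": self.counts.tp, "FP": self.counts.fp,
            "TN": self.counts.tn, "FN": self.counts.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "FPR": self.fpr,
            "specificity": self.specificity,
            "AUROC": self.auroc, "AUPR": self.aupr,
        }


def _as_binary(values, name: str) -> np.ndarray:
    arr = np.asarray([v.value if hasattr(v, "value") else v for v in values],
                     dtype=int)
    if arr.ndim != 1 or not np.isin(arr, (0, 1)).all():
        raise InputError(f"{name} must be a vector of 0/1 labels")
    return arr


def confusion(preds, labels) -> ConfusionCounts:
    """Exact confusion counts from predicted and actual binary labels."""
    p = _as_binary(preds, "predictions")
    y = _as_binary(labels, "labels")
    if p.shape != y.shape:
        raise InputError("prediction and label vectors must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (y == 1))),
        fp=int(np.sum((p == 1) & (y == 0))),
        tn=int(np.sum((p == 0) & (y == 0))),
        fn=int(np.sum((p == 0) & (y == 1))))


def _roc_points(scores: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    # group tied scores at one threshold
    distinct = np.r_[np.flatnonzero(np.diff(s) != 0), len(s) - 1]
    cum_tp = np.cumsum(yy)[distinct]
    cum_fp = (distinct + 1) - cum_tp
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    tpr = cum_tp / n_pos if n_pos else np.full(len(distinct), math.nan)
    fpr = cum_fp / n_neg if n_neg else np.full(len(distinct), math.nan)
    return pd.DataFrame({
        "threshold": np.r_[np.inf, s[distinct]],
        "fpr": np.r_[0.0, fpr],
        "tpr": np.r_[0.0, tpr],
        "_tp": np.r_[0, cum_tp],
    })


def metrics(scores, labels, cutoff: float = 0.5) -> MetricsReport:
    """Full metric suite for probability scores against binary labels.

    Threshold metrics are computed at ``cutoff`` with the >= rule; AUROC by
    trapezoidal integration of the ROC curve over all score thresholds, AUPR
    by the precision-recall step integral.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels, "labels")
    if scores.shape != y.shape:
        raise InputError("scores and labels must have equal length")
    if scores.size == 0:
        raise InputError("cannot evaluate an empty prediction set")
    if np.any(scores < 0) or np.any(scores > 1):
        raise InputError("scores must be probabilities in [0, 1]")

    preds = (scores >= cutoff).astype(int)
    c = confusion(preds, y)
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    if c.tp + c.fn:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall = math.nan  # no actual positives
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) else math.nan
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else math.nan

    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    roc = _roc_points(scores, y)
    if n_pos and n_neg:
        auroc = float(np.trapezoid(roc["tpr"], roc["fpr"]))
    else:
        auroc = math.nan
    if n_pos:
        # precision_i = TP_i / rank_i at each distinct threshold
        order = np.argsort(-scores, kind="stable")
        yy = y[order]
        distinct = np.r_[np.flatnonzero(np.diff(scores[order]) != 0),
                         len(scores) - 1]
        tp_i = np.cumsum(yy)[distinct]
        rank_i = distinct + 1
        prec_i = tp_i / rank_i
        rec_i = tp_i / n_pos
        pr = pd.DataFrame({"threshold": scores[order][distinct],
                           "recall": rec_i, "precision": prec_i})
        steps = np.diff(np.r_[0.0, rec_i])
        aupr = float(np.sum(steps * prec_i))
    else:
        pr = pd.DataFrame(columns=["threshold", "recall", "precision"])
        aupr = math.nan

    roc_out = roc[["threshold", "fpr", "tpr"]].copy()
    return MetricsReport(counts=c, accuracy=accuracy, precision=precision,
                         recall=recall, fpr=fpr, specificity=specificity,
                         auroc=auroc, aupr=aupr, roc_curve=roc_out,
                         pr_curve=pr)


# ---------------------------------------------------------------------------
# Split-level evaluation

def _fresh_model(spec: ArchitectureSpec, seed: int) -> NeuralClassifier:
    return NeuralClassifier(spec, seed=seed)


def evaluate_split(spec: ArchitectureSpec, config: TrainConfig,
                   plan: SplitPlan, inputs: ModelInput,
                   cutoff: float = 0.5) -> tuple[pd.DataFrame, dict]:
    """Train and evaluate per the split plan; returns (table, reports).

    Group schemes (leave-one-tissue-out / -chemotype-out) and k-fold train a
    fresh model on each fold's complement and evaluate on the held-out fold;
    the random 60/10/30 scheme trains once on train (validating on val) and
    evaluates on test.  The table has one row per fold plus a ``mean`` row.
    """
    rows, reports = [], {}
    n = len(inputs)

    def run(name, train_idx, test_idx, validation=None):
        model = _fresh_model(spec, seed=config.seed)
        cfg = config if validation is None else \
            TrainConfig(**{**config.__dict__, "validation": validation})
        model.fit(inputs.take(train_idx), cfg)
        proba = model.predict_proba(inputs.take(test_idx))
        rep = metrics(proba, inputs.y[test_idx], cutoff=cutoff)
        reports[name] = rep
        rows.append({"fold": name, "n_train": len(train_idx),
                     "n_test": len(test_idx), **rep.to_dict()})

    if plan.scheme == "random-60-10-30":
        run("test", plan["train"], plan["test"],
            validation=inputs.take(plan["val"]))
    elif plan.scheme in ("kfold-10", "leave-one-tissue-out",
                         "leave-one-chemotype-out"):
        for name in plan.names:
            test_idx = plan[name]
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            run(name, np.flatnonzero(mask), test_idx)
    elif plan.scheme == "monte-carlo":
        for name in plan.names:
            if not name.endswith("_train"):
                continue
            tag = name[:-len("_train")]
            run(tag, plan[name], plan[tag + "_test"])
    else:
        raise InputError(f"evaluate_split does not handle scheme {plan.scheme!r}")

    table = pd.DataFrame(rows)
    numeric = table.select_dtypes("number").mean(numeric_only=True)
    mean_row = {"fold": "mean", **numeric.to_dict()}
    table = pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
    return table, reports


def scrambled_control(inputs: ModelInput, spec: ArchitectureSpec,
                      config: TrainConfig, seed: int = 1234) -> MetricsReport:
    """Label-permutation control: scramble labels preserving class counts,
    split 60/10/30, train, and report held-out test metrics.

    A sound pipeline collapses to chance here: AUROC near 0.5 and, with an
    imbalanced class ratio, all-negative predictions (specificity 1,
    precision 0)."""
    scrambled = scramble_labels(inputs, seed=seed)
    plan = split(scrambled, "random-60-10-30", seed=seed)
    model = _fresh_model(spec, seed=config.seed)
    cfg = TrainConfig(**{**config.__dict__,
                         "validation": scrambled.take(plan["val"])})
    model.fit(scrambled.take(plan["train"]), cfg)
    proba = model.predict_proba(scrambled.take(plan["test"]))
    return metrics(proba, scrambled.y[plan["test"]])
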