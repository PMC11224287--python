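"""AUC-ROC scoring and per-fold report aggregation.

AUC is computed by the Mann-Whitney identity: the probability that a
randomly drawn positive outscores a randomly drawn negative, with half
credit for ties.  This is exactly the area under the ROC curve with
trapezoidal interpolation, and is invariant under any strictly
increasing rescaling of the scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledPredictions",
    "UndefinedAUCError",
    "auc_roc",
    "roc_points",
    "EvaluationReport",
    "summarize",
]


class UndefinedAUCError(ValueError):
    """AUC requested for a single-class label vector."""


@dataclass(frozen=True)
class LabeledPredictions:
    """Paired ground-truth binary labels and predicted scores in [0, 1]."""

    y_true: np.ndarray
    y_score: np.ndarray

    def __post_init__(self):
        yt = np.asarray(self.y_true, dtype=float)
        ys = np.asarray(self.y_score, dtype=float)
        if yt.ndim != 1 or yt.shape != ys.shape:
            raise ValueError(
                f"labels/scores must be 1-D of equal length: {yt.shape} vs {ys.shape}")
        if yt.size < 1:
            raise ValueError("need at least one prediction")
        if not np.isin(yt, (0.0, 1.0)).all():
            raise ValueError("labels must be binary 0/1")
        if np.any((ys < 0) | (ys > 1)):
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "y_true", yt)
        object.__setattr__(self, "y_score", ys)


def _unpack(y_true, y_score):
    if y_score is None:
        y_true, y_score = y_true.y_true, y_true.y_score
    yt = np.asarray(y_true, dtype=float).ravel()
    ys = np.asarray(y_score, dtype=float).ravel()
    if yt.shape != ys.shape:
        raise ValueError(f"length mismatch: {yt.size} labels vs {ys.size} scores")
    return yt, ys


def auc_roc(y_true, y_score=None) -> float:
    """Area under the ROC curve via midranks.

    Equals (#concordant positive-negative pairs + 0.5 * #tied pairs)
    divided by (P * N).  Raises :class:`UndefinedAUCError` when only one
    class is present -- an undefined AUC is never silently reported as 0.5.
    """
    yt, ys = _unpack(y_true, y_score)
    pos = yt == 1
    n_pos = int(pos.sum())
    n_neg = yt.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"AUC undefined: {n_pos} positives and {n_neg} negatives")
    ranks = _midranks(ys)
    # Mann-Whitney U statistic of the positives, normalised
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _midranks(x: np.ndarray) -> np.ndarray:
    """1-based ranks with ties assigned the average rank of their block."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    block_start = np.flatnonzero(np.r_[True, xs[1:] != xs[:-1]])
    block_end = np.r_[block_start[1:], xs.size]
    mid = (block_start + 1 + block_end) / 2.0
    ranks = np.empty(x.size)
    ranks[order] = np.repeat(mid, block_end - block_start)
    return ranks


def roc_points(y_true, y_score=None) -> np.ndarray:
    """(FPR, TPR) points of the empirical ROC curve, threshold-descending."""
    yt, ys = _unpack(y_true, y_score)
    n_pos = (yt == 1).sum()
    n_neg = (yt == 0).sum()
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("ROC undefined for a single-class label vector")
    order = np.argsort(-ys, kind="mergesort")
    yt, ys = yt[order], ys[order]
    distinct = np.r_[np.flatnonzero(ys[1:] != ys[:-1]), ys.size - 1]
    tpr = np.cumsum(yt)[distinct] / n_pos
    fpr = np.cumsum(1 - yt)[distinct] / n_neg
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])


@dataclass(frozen=True)
class EvaluationReport:
    """Per-fold AUCs and their mean for one model variant / epoch budget."""

    model_name: str
    epoch_budget: int
    fold_aucs: tuple[float, ...]
    seed: int
    mean_auc: float = field(init=False)

    def __post_init__(self):
        aucs = tuple(float(a) for a in self.fold_aucs)
        if not aucs:
            raise ValueError("fold_aucs must be non-empty")
        if any(not 0.0 <= a <= 1.0 for a in aucs):
            raise ValueError(f"AUCs must lie in [0, 1]: {aucs}")
        object.__setattr__(self, "fold_aucs", aucs)
        object.__setattr__(self, "mean_auc", float(np.mean(aucs)))

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "epoch_budget": self.epoch_budget,
            "fold_aucs": list(self.fold_aucs),
            "mean_auc": self.mean_auc,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        lines = ["rotation\ttest_auc"]
        for i, a in enumerate(self.fold_aucs):
            lines.append(f"{i}\t{a:.6f}")
        lines.append(f"mean\t{self.mean_auc:.6f}")
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        lines = [
            f"Cross-validation report: {self.model_name}",
            f"  epoch budget : {self.epoch_budget}",
            f"  seed         : {self.seed}",
            f"  folds        : {len(self.fold_aucs)}",
            "  fold AUCs    : " + ", ".join(f"{a:.4f}" for a in self.fold_aucs),
            f"  mean AUC     : {self.mean_auc:.4f}",
        ]
        return "\n".join(lines)


def summarize(fold_aucs, *, model_name: str = "dsc", epoch_budget: int = 0,
              seed: int = 0) -> EvaluationReport:
    """Aggregate per-fold AUCs into an :class:`EvaluationReport`."""
    return EvaluationReport(model_name=model_name, epoch_budget=epoch_budget,
                            fold_aucs=tuple(fold_aucs), seed=seed)
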