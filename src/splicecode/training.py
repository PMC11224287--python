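"""10-fold cross-validation with a dedicated early-stopping fold.

The dataset is shuffled once (seeded) and split round-robin into ten
folds of near-identical size.  Rotation ``r`` tests on fold ``r``,
monitors early stopping on fold ``(r + 1) mod 10`` and trains on the
remaining eight folds, so every sample is tested exactly once and the
three roles never overlap.

Training minimises binary cross-entropy with Adam (learning rate 5e-4,
betas 0.9/0.999, epsilon 1e-8, no decay by default).  After each epoch
the loss on the early-stopping fold is evaluated; when it has not
improved by at least ``min_delta`` for ``patience`` consecutive epochs,
training halts and the weights from the best early-stopping epoch are
restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .architecture import (DSCConfig, DualBranchNet, binary_cross_entropy,
                           build_baseline, build_dsc)
from .encoding import encode_dataset
from .evaluation import EvaluationReport, UndefinedAUCError, auc_roc, summarize

__all__ = [
    "N_FOLDS",
    "FoldPlan",
    "Rotation",
    "TrainingHistory",
    "DivergenceError",
    "make_fold_plan",
    "train_fold",
    "run_cv",
    "epoch_sweep",
    "EpochSweepResult",
]

N_FOLDS = 10
DEFAULT_BATCH_SIZE = 64
DEFAULT_PATIENCE = 10
DEFAULT_MIN_DELTA = 1e-4


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class Rotation:
    """Role assignment of the ten folds for one cross-validation rotation."""

    train_folds: tuple[int, ...]
    earlystop_fold: int
    test_fold: int


@dataclass(frozen=True)
class FoldPlan:
    """Seeded partition of ``n_samples`` into ten folds plus the ten
    train / early-stop / test rotations."""

    n_samples: int
    fold_of: np.ndarray
    rotations: tuple[Rotation, ...]
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def fold_sizes(self) -> list[int]:
        return [int((self.fold_of == f).sum()) for f in range(N_FOLDS)]

    def rotation_indices(self, r: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rot = self.rotations[r]
        train = np.flatnonzero(np.isin(self.fold_of, rot.train_folds))
        return train, self.fold_indices(rot.earlystop_fold), self.fold_indices(rot.test_fold)


def make_fold_plan(n_samples: int, seed: int) -> FoldPlan:
    """Shuffle sample indices (seeded) and deal them round-robin into
    ten folds; fold sizes differ by at most one."""
    if n_samples < N_FOLDS:
        raise ValueError(
            f"need at least {N_FOLDS} samples for {N_FOLDS}-fold CV, got {n_samples}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    fold_of = np.empty(n_samples, dtype=np.int64)
    fold_of[perm] = np.arange(n_samples) % N_FOLDS
    rotations = tuple(
        Rotation(
            train_folds=tuple(f for f in range(N_FOLDS)
                              if f != r and f != (r + 1) % N_FOLDS),
            earlystop_fold=(r + 1) % N_FOLDS,
            test_fold=r,
        )
        for r in range(N_FOLDS)
    )
    return FoldPlan(n_samples=n_samples, fold_of=fold_of, rotations=rotations,
                    seed=seed)


@dataclass
class TrainingHistory:
    """Per-epoch traces of one training run."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    earlystop_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    max_epochs: int = 0


def _take(data, idx):
    x1, x2, x3, y = data
    return x1[idx], x2[idx], x3[idx], y[idx]


def _as_arrays(data):
    """Accept either a list of records or a pre-encoded (X1, X2, X3, y) tuple."""
    if isinstance(data, tuple) and len(data) == 4:
        return data
    return encode_dataset(data)


def train_fold(model: DualBranchNet, train_data, earlystop_data,
               config: DSCConfig | None = None, max_epochs: int = 100,
               seed=0, *, batch_size: int = DEFAULT_BATCH_SIZE,
               patience: int = DEFAULT_PATIENCE,
               min_delta: float = DEFAULT_MIN_DELTA):
    """Train ``model`` with Adam and early stopping on a held-out fold.

    Returns ``(model, TrainingHistory)`` with the model carrying the
    weights of the epoch with the best early-stopping loss.
    """
    if config is None:
        config = model.config
    x1, x2, x3, y = _as_arrays(train_data)
    ex1, ex2, ex3, ey = _as_arrays(earlystop_data)
    n = y.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if ey.shape[0] == 0:
        raise ValueError("empty early-stopping set")

    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), model.gradients(),
                  learning_rate=config.learning_rate, beta1=config.beta1,
                  beta2=config.beta2, epsilon=config.epsilon, decay=config.decay)

    history = TrainingHistory(max_epochs=max_epochs)
    best_loss = np.inf
    best_weights = model.get_weights()
    wait = 0

    for epoch in range(1, max_epochs + 1):
        perm = rng.permutation(n)
        loss_sum = 0.0
        correct = 0
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            logits = model.forward_logits(x1[idx], x2[idx], x3[idx],
                                          train=True, rng=rng)
            p = nn.sigmoid(logits)
            yb = y[idx]
            loss = binary_cross_entropy(yb, p)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            loss_sum += loss * idx.size
            correct += int(((p >= 0.5) == (yb == 1)).sum())
            model.backward((p - yb) / idx.size)
            opt.step()

        history.train_loss.append(loss_sum / n)
        history.train_accuracy.append(correct / n)

        es_p = _predict_proba_batched(model, ex1, ex2, ex3, batch_size)
        es_loss = binary_cross_entropy(ey, es_p)
        if not np.isfinite(es_loss):
            raise DivergenceError(f"non-finite early-stop loss at epoch {epoch}")
        history.earlystop_loss.append(es_loss)
        history.stopped_epoch = epoch

        if es_loss < best_loss - min_delta:
            best_loss = es_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break

    model.set_weights(best_weights)
    return model, history


def _predict_proba_batched(model, x1, x2, x3, batch_size=256):
    out = np.empty(x1.shape[0])
    for start in range(0, x1.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        out[sl] = model.predict_proba(x1[sl], x2[sl], x3[sl])
    return out


_BUILDER_NAMES = {"build_dsc": "dsc", "build_baseline": "baseline"}


def run_cv(records, config: DSCConfig | None = None, max_epochs: int = 10,
           seed: int = 0, model_builder=build_dsc, *,
           batch_size: int = DEFAULT_BATCH_SIZE, patience: int = DEFAULT_PATIENCE,
           min_delta: float = DEFAULT_MIN_DELTA, progress=None) -> EvaluationReport:
    """Full 10-rotation cross-validation of one model variant.

    ``records`` may be a list of :class:`SpliceEventRecord` or an
    already-encoded ``(X1, X2, X3, y)`` tuple.  A fresh model is built
    and trained for each rotation; the report holds the ten test-fold
    AUCs and their mean.
    """
    data = _as_arrays(records)
    n = data[3].shape[0]
    plan = make_fold_plan(n, seed)
    name = _BUILDER_NAMES.get(getattr(model_builder, "__name__", ""), "custom")

    aucs = []
    for r in range(N_FOLDS):
        train_idx, es_idx, test_idx = plan.rotation_indices(r)
        # leakage guard: the three role sets must never overlap
        assert not (set(train_idx) & set(test_idx))
        assert not (set(train_idx) & set(es_idx))
        assert not (set(es_idx) & set(test_idx))

        model = model_builder(config, rng=np.random.default_rng([seed, r, 0]))
        try:
            model, _ = train_fold(model, _take(data, train_idx), _take(data, es_idx),
                                  max_epochs=max_epochs,
                                  seed=np.random.default_rng([seed, r, 1]),
                                  batch_size=batch_size, patience=patience,
                                  min_delta=min_delta)
            tx1, tx2, tx3, ty = _take(data, test_idx)
            scores = _predict_proba_batched(model, tx1, tx2, tx3)
            auc = auc_roc(ty, scores)
        except (UndefinedAUCError, DivergenceError) as err:
            raise type(err)(f"rotation {r}: {err}") from err
        aucs.append(auc)
        if progress is not None:
            progress(r, auc)

    return summarize(aucs, model_name=name, epoch_budget=max_epochs, seed=seed)


@dataclass(frozen=True)
class EpochSweepResult:
    """Epoch-budget sweep over both model variants."""

    table: pd.DataFrame
    reports: dict

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=True)


def epoch_sweep(records, config: DSCConfig | None = None,
                epochs_list=(10, 50, 100, 150, 200), seed: int = 0, *,
                builders=None, progress=None, **train_kwargs) -> EpochSweepResult:
    """Run ``run_cv`` for each epoch budget and each model variant.

    Produces a table with one row per epoch budget and the mean AUC of
    the existing (six-hidden-layer) and updated (eight-hidden-layer)
    models as columns.
    """
    epochs_list = tuple(int(e) for e in epochs_list)
    if not epochs_list:
        raise ValueError("epochs_list must be non-empty")
    if builders is None:
        builders = {"existing": build_baseline, "updated": build_dsc}

    data = _as_arrays(records)
    reports: dict[tuple[int, str], EvaluationReport] = {}
    rows = {}
    for epochs in epochs_list:
        row = {}
        for col, builder in builders.items():
            rep = run_cv(data, config, max_epochs=epochs, seed=seed,
                         model_builder=builder, **train_kwargs)
            reports[(epochs, col)] = rep
            row[f"{col}_mean_auc"] = rep.mean_auc
            if progress is not None:
                progress(epochs, col, rep.mean_auc)
        rows[epochs] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "epochs"
    return EpochSweepResult(table=table, reports=reports)
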