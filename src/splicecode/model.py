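"""Model/Results facade over the dual-branch splice-event classifier.

Mirrors the fit-then-inspect idiom of statistical modelling packages:
a :class:`SpliceEventClassifier` is constructed from data, ``fit()``
trains it and returns a :class:`SpliceClassifierResults` holding the
trained network, the training history and prediction/summary methods,
and ``cross_validate()`` runs the full 10-fold protocol.
"""

from __future__ import annotations

import numpy as np

from . import training
from .architecture import (DSCConfig, build_baseline, build_dsc, model_summary,
                           summary_to_tsv)
from .encoding import encode_dataset, read_dataset
from .evaluation import EvaluationReport, auc_roc
from .training import TrainingHistory, train_fold

__all__ = ["SpliceEventClassifier", "SpliceClassifierResults"]

_BUILDERS = {"dsc": build_dsc, "baseline": build_baseline}


class SpliceEventClassifier:
    """Dual-branch convolutional classifier of splice-event inclusion.

    Parameters
    ----------
    records : list of SpliceEventRecord
        The labeled events to model.
    config : DSCConfig, optional
        Architecture/optimizer hyperparameters; defaults to the
        eight-hidden-layer variant's published settings.
    variant : {"dsc", "baseline"}
        Which architecture to build: the eight-hidden-layer network or
        the six-hidden-layer predecessor.
    """

    def __init__(self, records, config: DSCConfig | None = None,
                 variant: str = "dsc") -> None:
        if variant not in _BUILDERS:
            raise ValueError(f"unknown variant {variant!r}; expected one of "
                             f"{sorted(_BUILDERS)}")
        self.records = list(records)
        self.config = config
        self.variant = variant
        self.data = encode_dataset(self.records)

    @classmethod
    def from_files(cls, sequences_path, annotations_path, *,
                   config: DSCConfig | None = None, variant: str = "dsc"):
        """Build the model from a FASTA + TSV dataset on disk."""
        return cls(read_dataset(sequences_path, annotations_path),
                   config=config, variant=variant)

    @property
    def nobs(self) -> int:
        return len(self.records)

    def _builder(self):
        return _BUILDERS[self.variant]

    def fit(self, max_epochs: int = 100, seed: int = 0, *,
            earlystop_fraction: float = 0.1,
            batch_size: int = training.DEFAULT_BATCH_SIZE,
            patience: int = training.DEFAULT_PATIENCE,
            min_delta: float = training.DEFAULT_MIN_DELTA) -> "SpliceClassifierResults":
        """Train on a seeded split, holding out ``earlystop_fraction``
        of the events for early stopping."""
        if not 0.0 < earlystop_fraction < 1.0:
            raise ValueError("earlystop_fraction must lie in (0, 1)")
        n = self.nobs
        n_es = max(1, int(round(n * earlystop_fraction)))
        if n - n_es < 1:
            raise ValueError("not enough events to split off an early-stop set")
        perm = np.random.default_rng([seed, 0]).permutation(n)
        es_idx, tr_idx = perm[:n_es], perm[n_es:]

        net = self._builder()(self.config, rng=np.random.default_rng([seed, 1]))
        net, history = train_fold(
            net, training._take(self.data, tr_idx), training._take(self.data, es_idx),
            max_epochs=max_epochs, seed=np.random.default_rng([seed, 2]),
            batch_size=batch_size, patience=patience, min_delta=min_delta)
        return SpliceClassifierResults(self, net, history, seed=seed)

    def cross_validate(self, max_epochs: int = 10, seed: int = 0,
                       **kwargs) -> EvaluationReport:
        """Run the full 10-rotation cross-validation protocol."""
        return training.run_cv(self.data, self.config, max_epochs=max_epochs,
                               seed=seed, model_builder=self._builder(), **kwargs)


class SpliceClassifierResults:
    """Fit results: the trained network, its history and diagnostics."""

    def __init__(self, model: SpliceEventClassifier, network,
                 history: TrainingHistory, seed: int) -> None:
        self.model = model
        self.network = network
        self.history = history
        self.seed = seed

    def predict(self, records=None) -> np.ndarray:
        """Inclusion probabilities for ``records`` (default: training data)."""
        data = self.model.data if records is None else encode_dataset(records)
        return training._predict_proba_batched(self.network, *data[:3])

    def score_auc(self, records) -> float:
        """AUC-ROC of the fitted network on held-out records."""
        data = encode_dataset(records)
        return auc_roc(data[3], training._predict_proba_batched(self.network, *data[:3]))

    def save_weights(self, path) -> None:
        self.network.save_weights(path)

    def layer_table(self):
        return model_summary(self.network)

    def summary(self) -> str:
        """Human-readable fit summary: data, training trace, layer table."""
        h = self.history
        lines = [
            f"SpliceEventClassifier results ({self.model.variant} variant)",
            f"  events        : {self.model.nobs}",
            f"  seed          : {self.seed}",
            f"  epochs run    : {h.stopped_epoch} / {h.max_epochs} "
            f"(best early-stop epoch {h.best_epoch})",
            f"  final train loss / acc : {h.train_loss[-1]:.4f} / "
            f"{h.train_accuracy[-1]:.4f}",
            f"  best early-stop loss   : {min(h.earlystop_loss):.4f}",
            "",
            summary_to_tsv(self.network).rstrip("\n"),
        ]
        return "\n".join(lines)
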