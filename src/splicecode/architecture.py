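"""Dual-branch convolutional architectures for splice-event classification.

The classifier reads two fixed-length one-hot encoded sequence windows
through two mirrored convolutional branches, concatenates the branch
feature maps with three scalar length features, and emits a single
sigmoid inclusion probability.  Two variants are provided:

``build_dsc``
    The eight-hidden-layer network: four conv blocks per branch with
    filters (8, 16, 32, 64) and kernels (7, 4, 3, 2).  Each block is
    convolution -> dropout -> ReLU -> max-pool(2, 2), in that order.

``build_baseline``
    The earlier six-hidden-layer network: three conv blocks per branch
    with filters (32, 8, 8), kernels (7, 4, 3) and dropout 0.2.

With the default configuration the per-layer output shapes and
trainable parameter counts are fixed by construction: conv layers
232 / 528 / 1,568 / 4,160 parameters per branch, a flattened merged
feature vector of length 896 (899 after appending the length features),
and dense layers of 921,600 and 1,025 parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import Conv1D, Dense, Dropout, MaxPool1D, ReLU

__all__ = [
    "DSCConfig",
    "ModelSummaryRow",
    "ArchitectureError",
    "DualBranchNet",
    "build_dsc",
    "build_baseline",
    "model_summary",
    "summary_to_tsv",
    "binary_cross_entropy",
    "BCE_EPSILON",
]

#: scores are clipped to [eps, 1 - eps] before taking logs
BCE_EPSILON = 1e-7


class ArchitectureError(ValueError):
    """A kernel/pool cascade drove a temporal dimension below 1."""


@dataclass(frozen=True)
class DSCConfig:
    """Every architecture and optimizer hyperparameter of the classifier.

    Defaults are the eight-hidden-layer variant: branch filters
    (8, 16, 32, 64) with kernels (7, 4, 3, 2), pool size/stride 2,
    a 1,024-unit dense layer with dropout 0.5, and Adam at learning
    rate 5e-4, betas (0.9, 0.999), epsilon 1e-8, no decay.
    """

    branch_filters: tuple[int, ...] = (8, 16, 32, 64)
    branch_kernels: tuple[int, ...] = (7, 4, 3, 2)
    pool_size: int = 2
    pool_stride: int = 2
    conv_dropout: float = 0.2
    dense_units: int = 1024
    dense_dropout: float = 0.5
    learning_rate: float = 5e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    decay: float = 0.0
    seq_len: int = 140
    n_channels: int = 4
    n_extra_features: int = 3

    def __post_init__(self):
        object.__setattr__(self, "branch_filters", tuple(self.branch_filters))
        object.__setattr__(self, "branch_kernels", tuple(self.branch_kernels))
        if len(self.branch_filters) != len(self.branch_kernels):
            raise ValueError(
                "branch_filters and branch_kernels must have equal length "
                f"({len(self.branch_filters)} != {len(self.branch_kernels)})")
        if not self.branch_filters:
            raise ValueError("at least one conv layer per branch is required")
        for name in ("branch_filters", "branch_kernels"):
            vals = getattr(self, name)
            if any(int(v) != v or v < 1 for v in vals):
                raise ValueError(f"{name} must be positive integers: {vals}")
        for name in ("pool_size", "pool_stride", "dense_units", "seq_len",
                     "n_channels", "n_extra_features"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("conv_dropout", "dense_dropout"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must lie in [0, 1): {rate}")

    def replace(self, **kwargs) -> "DSCConfig":
        return replace(self, **kwargs)


#: the six-hidden-layer predecessor, expressed in the same config space
BASELINE_CONFIG = DSCConfig(branch_filters=(32, 8, 8), branch_kernels=(7, 4, 3),
                            conv_dropout=0.2)


@dataclass(frozen=True)
class ModelSummaryRow:
    layer_name: str
    output_shape: tuple[int, ...]
    param_count: int


class DualBranchNet:
    """Two mirrored conv branches merged with extra scalar features.

    Not a generic graph engine: the topology is fixed and the forward /
    backward passes are written out explicitly, which keeps the
    implementation auditable against the layer table.
    """

    def __init__(self, config: DSCConfig, rng: np.random.Generator) -> None:
        self.config = config
        c = config
        rows: list[ModelSummaryRow] = [
            ModelSummaryRow("input_a", (c.seq_len, c.n_channels), 0),
            ModelSummaryRow("input_b", (c.seq_len, c.n_channels), 0),
        ]

        def make_branch(tag: str) -> list[nn.Layer]:
            layers: list[nn.Layer] = []
            length, channels = c.seq_len, c.n_channels
            for i, (f, k) in enumerate(zip(c.branch_filters, c.branch_kernels), 1):
                conv = Conv1D(channels, f, k, rng)
                length = length - k + 1
                if length < 1:
                    raise ArchitectureError(
                        f"{tag}/conv{i}: kernel {k} drives temporal length to "
                        f"{length} (< 1)")
                layers += [conv, Dropout(c.conv_dropout), ReLU(),
                           MaxPool1D(c.pool_size, c.pool_stride)]
                conv_len = length
                length //= c.pool_size
                if length < 1:
                    raise ArchitectureError(
                        f"{tag}/pool{i}: pooling length {conv_len} below size "
                        f"{c.pool_size}")
                channels = f
                if tag == "branch_a":  # one summary block per mirrored pair
                    rows.extend([
                        ModelSummaryRow(f"branch_a/conv{i}", (conv_len, f), conv.n_params),
                        ModelSummaryRow(f"branch_b/conv{i}", (conv_len, f), conv.n_params),
                        ModelSummaryRow(f"branch_a/dropout{i}", (conv_len, f), 0),
                        ModelSummaryRow(f"branch_b/dropout{i}", (conv_len, f), 0),
                        ModelSummaryRow(f"branch_a/relu{i}", (conv_len, f), 0),
                        ModelSummaryRow(f"branch_b/relu{i}", (conv_len, f), 0),
                        ModelSummaryRow(f"branch_a/maxpool{i}", (length, f), 0),
                        ModelSummaryRow(f"branch_b/maxpool{i}", (length, f), 0),
                    ])
            self._branch_out = (length, channels)
            return layers

        self.branch_a = make_branch("branch_a")
        self.branch_b = make_branch("branch_b")

        length, channels = self._branch_out
        flat = length * channels * 2
        merged = flat + c.n_extra_features
        self.dense_hidden = Dense(merged, c.dense_units, rng)
        self.head = [self.dense_hidden, ReLU(), Dropout(c.dense_dropout)]
        self.dense_out = Dense(c.dense_units, 1, rng)

        rows.extend([
            ModelSummaryRow("concatenate_branches", (length, channels * 2), 0),
            ModelSummaryRow("flatten", (flat,), 0),
            ModelSummaryRow("input_features", (c.n_extra_features,), 0),
            ModelSummaryRow("concatenate_features", (merged,), 0),
            ModelSummaryRow("dense_hidden", (c.dense_units,), self.dense_hidden.n_params),
            ModelSummaryRow("dense_dropout", (c.dense_units,), 0),
            ModelSummaryRow("dense_output", (1,), self.dense_out.n_params),
        ])
        self._summary = rows
        self.flat_len = flat
        self.merged_len = merged

    # -- parameter plumbing -------------------------------------------------

    def _all_layers(self) -> list[nn.Layer]:
        return [*self.branch_a, *self.branch_b, *self.head, self.dense_out]

    def parameters(self) -> list[np.ndarray]:
        return [p for lay in self._all_layers() for p in lay.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for lay in self._all_layers() for g in lay.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match model parameters")
        for p, w in zip(params, weights):
            p[...] = w

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x1, x2, x3, *, train: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        a = np.asarray(x1, dtype=nn.DTYPE)
        b = np.asarray(x2, dtype=nn.DTYPE)
        for lay in self.branch_a:
            a = lay.forward(a, train=train, rng=rng)
        for lay in self.branch_b:
            b = lay.forward(b, train=train, rng=rng)
        h = np.concatenate([a, b], axis=2)
        self._merge_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = np.concatenate([h, np.asarray(x3, dtype=nn.DTYPE)], axis=1)
        for lay in self.head:
            h = lay.forward(h, train=train, rng=rng)
        return self.dense_out.forward(h, train=train, rng=rng)[:, 0]

    def predict_proba(self, x1, x2, x3, *, train: bool = False,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        return nn.sigmoid(self.forward_logits(x1, x2, x3, train=train, rng=rng))

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logits); gradients land in .gradients()."""
        d = self.dense_out.backward(dlogits[:, None].astype(nn.DTYPE))
        for lay in reversed(self.head):
            d = lay.backward(d)
        d, _ = d[:, :self.flat_len], d[:, self.flat_len:]
        d = d.reshape(self._merge_shape)
        half = self._merge_shape[2] // 2
        da, db = d[:, :, :half], d[:, :, half:]
        for lay in reversed(self.branch_a):
            da = lay.backward(da)
        for lay in reversed(self.branch_b):
            db = lay.backward(db)

    # -- persistence ---------------------------------------------------------

    def save_weights(self, path) -> None:
        np.savez(path, **{f"p{i}": p for i, p in enumerate(self.parameters())})

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.set_weights([data[f"p{i}"] for i in range(len(self.parameters()))])


def build_dsc(config: DSCConfig | None = None, *,
              rng: np.random.Generator | None = None, seed: int = 0) -> DualBranchNet:
    """Build the eight-hidden-layer dual-branch classifier."""
    if config is None:
        config = DSCConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    return DualBranchNet(config, rng)


def build_baseline(config: DSCConfig | None = None, *,
                   rng: np.random.Generator | None = None, seed: int = 0) -> DualBranchNet:
    """Build the six-hidden-layer predecessor (filters 32/8/8, kernels 7/4/3)."""
    if config is None:
        config = BASELINE_CONFIG
    else:
        config = config.replace(branch_filters=BASELINE_CONFIG.branch_filters,
                                branch_kernels=BASELINE_CONFIG.branch_kernels,
                                conv_dropout=BASELINE_CONFIG.conv_dropout)
    if rng is None:
        rng = np.random.default_rng(seed)
    return DualBranchNet(config, rng)


def model_summary(model: DualBranchNet) -> list[ModelSummaryRow]:
    """One row per layer in construction order (mirrored branches interleaved)."""
    return list(model._summary)


def summary_to_tsv(model: DualBranchNet) -> str:
    lines = ["layer\toutput_shape\tparams"]
    for row in model_summary(model):
        shape = "(" + ", ".join(str(d) for d in row.output_shape) + ")"
        lines.append(f"{row.layer_name}\t{shape}\t{row.param_count}")
    total = sum(r.param_count for r in model_summary(model))
    lines.append(f"total\t\t{total}")
    return "\n".join(lines) + "\n"


def _as_label_score(y_true, y_score):
    if y_score is None:  # a LabeledPredictions-like object
        y_true, y_score = y_true.y_true, y_true.y_score
    yt = np.asarray(y_true, dtype=float)
    ys = np.asarray(y_score, dtype=float)
    if yt.shape != ys.shape or yt.ndim != 1:
        raise ValueError(
            f"labels and scores must be 1-D of equal length: {yt.shape} vs {ys.shape}")
    if yt.size < 1:
        raise ValueError("need at least one sample")
    return yt, ys


def binary_cross_entropy(y_true, y_score=None, *, eps: float = BCE_EPSILON) -> float:
    """Mean binary cross-entropy, natural log.

    -(1/N) * sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ].  Each log
    argument is clipped below at ``eps`` so a hard wrong prediction
    yields a large finite loss rather than infinity; an exactly correct
    prediction contributes exactly zero.
    """
    yt, ys = _as_label_score(y_true, y_score)
    return float(-np.mean(yt * np.log(np.clip(ys, eps, 1.0))
                          + (1.0 - yt) * np.log(np.clip(1.0 - ys, eps, 1.0))))
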