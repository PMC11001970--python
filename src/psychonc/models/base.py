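"""Model specifications and class-imbalance handling.

All families share one inference contract: ``predict_proba`` maps
tokenized documents to scores in [0, 1], so evaluation code never
branches on the family.  Class imbalance is handled either by per-class
loss weights inversely proportional to class frequency, or by randomly
undersampling negatives to a 1:1 ratio with positives (every positive is
kept; nothing is duplicated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace  # noqa: F401

import numpy as np

FAMILIES = ("rule", "bow", "cnn", "lstm", "transformer", "meanpool")
IMBALANCE_MODES = ("loss_weighting", "undersample")
TRANSFORMER_TOKEN_LIMITS = (512, 1024, 2048, 4096)

#: preprocessing dialect consumed by each family
FAMILY_DIALECT = {"rule": "bow", "bow": "bow", "cnn": "neural",
                  "lstm": "neural", "transformer": "transformer",
                  "meanpool": "neural"}  # meanpool: internal linear baseline


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters and training regime for one model family."""

    family: str
    target: str
    imbalance_mode: str = "loss_weighting"
    patience: int = 5
    min_epochs: int = 0
    max_epochs: int = 100
    # cap on dev documents scored per epoch for early stopping (all
    # positives are kept; negatives are subsampled to fit the budget)
    dev_eval_max: int | None = None
    seed: int = 0
    max_tokens: int | None = None
    threshold: float = 0.5
    # bag-of-words
    C_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    min_df: int = 5
    scale_counts: bool = True  # variance-standardize count features
    # shared neural
    embed_dim: int = 16
    batch_size: int = 32
    learning_rate: float = 5e-3
    min_token_freq: int = 2
    dropout: float = 0.5
    # cnn
    conv_widths: tuple[int, ...] = (2, 3, 4)
    n_filters: int = 64
    # lstm / transformer pooling over time: "max" or "mean"
    pooling: str = "max"
    # lstm
    hidden_dim: int = 128
    # transformer
    n_positions: int = 512
    attn_dim: int | None = None
    ff_dim: int = 32

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.imbalance_mode not in IMBALANCE_MODES:
            raise ValueError(f"unknown imbalance_mode {self.imbalance_mode!r}")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.family == "transformer" and self.max_tokens is not None:
            if self.max_tokens not in TRANSFORMER_TOKEN_LIMITS:
                raise ValueError(
                    f"transformer max_tokens must be one of "
                    f"{TRANSFORMER_TOKEN_LIMITS}, got {self.max_tokens}")
            if self.max_tokens > self.n_positions:
                raise ValueError(
                    f"max_tokens={self.max_tokens} exceeds the encoder's "
                    f"positional capacity n_positions={self.n_positions}")

    @property
    def dialect(self) -> str:
        return FAMILY_DIALECT[self.family]


def rebalance(labels, mode: str, rng: np.random.Generator
              ) -> tuple[np.ndarray, np.ndarray]:
    """Return (kept indices, per-sample loss weights) for a training set.

    ``undersample``: all positives plus an equal-size random subset of
    negatives, unit weights.  ``loss_weighting``: every index kept, class
    weight n/(2 n_c) so the positive:negative weight ratio equals the
    inverse class-frequency ratio.
    """
    labels = np.asarray(labels, dtype=int)
    if mode not in IMBALANCE_MODES:
        raise ValueError(f"unknown imbalance mode {mode!r}")
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("training set must contain both classes")
    if mode == "undersample":
        if neg.size > pos.size:
            neg = rng.choice(neg, size=pos.size, replace=False)
        idx = np.sort(np.concatenate([pos, neg]))
        return idx, np.ones(idx.size)
    n = labels.size
    w_pos = n / (2.0 * pos.size)
    w_neg = n / (2.0 * neg.size)
    idx = np.arange(n)
    return idx, np.where(labels == 1, w_pos, w_neg)


class EarlyStopper:
    """Patience-based stopping on a maximized criterion (dev BAC).

    ``update`` returns True while training should continue; the best
    epoch and value are tracked so the best checkpoint can be restored.
    Epochs are 1-based.

    ``min_epochs`` keeps training alive through an initial flat stretch
    (dev BAC sits at 0.5 until the score distribution crosses the
    threshold); stopping is never triggered before it is reached.
    """

    def __init__(self, patience: int, min_epochs: int = 0):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_epochs = min_epochs
        self.best_value = -np.inf
        self.best_epoch = 0
        self.epoch = 0

    def update(self, value: float) -> bool:
        self.epoch += 1
        if value > self.best_value:
            self.best_value = value
            self.best_epoch = self.epoch
            return True
        if self.epoch < self.min_epochs:
            return True
        return (self.epoch - self.best_epoch) < self.patience
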