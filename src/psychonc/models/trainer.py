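"""Training harness for the numpy sequence models.

Wraps a net (CNN / BiLSTM / transformer / mean-pool) with an embedding
table, weighted binary cross-entropy, Adam, and patience-based early
stopping on development-set balanced accuracy.  The best-dev checkpoint
is restored at the end; ``epochs_trained`` records how many epochs ran
and ``best_epoch`` which checkpoint was kept.  Everything is
deterministic given the spec seed; dropout is disabled at inference.
"""

from __future__ import annotations

import numpy as np

from ..cohort import TokenSeq, truncate
from ..metrics import confusion_metrics
from .base import EarlyStopper, ModelSpec, rebalance
from .nets import Adam, BiLSTMNet, CNNNet, MeanPoolNet, TransformerNet

PAD, UNK = 0, 1


def _build_net(spec: ModelSpec):
    if spec.family == "cnn":
        return CNNNet(spec.embed_dim, widths=spec.conv_widths,
                      n_filters=spec.n_filters, dropout=spec.dropout)
    if spec.family == "lstm":
        return BiLSTMNet(spec.embed_dim, hidden_dim=spec.hidden_dim,
                         pooling=spec.pooling)
    if spec.family == "transformer":
        return TransformerNet(spec.embed_dim, n_positions=spec.n_positions,
                              attn_dim=spec.attn_dim, ff_dim=spec.ff_dim,
                              pooling=spec.pooling)
    if spec.family == "meanpool":  # internal, used by attribution tests
        return MeanPoolNet(spec.embed_dim)
    raise ValueError(f"no sequence net for family {spec.family!r}")


class SequenceModel:
    """A trainable sequence classifier with a shared predict contract."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.net = _build_net(spec)
        self.vocab_: dict[str, int] = {}
        self.params_: dict[str, np.ndarray] | None = None
        self.embedding_: np.ndarray | None = None
        self.best_dev_bac: float | None = None
        self.epochs_trained = 0
        self.best_epoch = 0

    # ---- encoding ---------------------------------------------------------

    def _limit(self) -> int | None:
        if self.spec.max_tokens is not None:
            return self.spec.max_tokens
        if self.spec.family == "transformer":
            return self.spec.n_positions
        return None

    def _build_vocab(self, token_seqs) -> None:
        freq: dict[str, int] = {}
        for seq in token_seqs:
            for tok in seq.tokens:
                freq[tok] = freq.get(tok, 0) + 1
        vocab = {"<pad>": PAD, "<unk>": UNK}
        for tok in sorted(freq):
            if freq[tok] >= self.spec.min_token_freq:
                vocab[tok] = len(vocab)
        self.vocab_ = vocab

    def _encode(self, seq: TokenSeq) -> np.ndarray:
        limit = self._limit()
        if limit is not None:
            seq = truncate(seq, limit)
        v = self.vocab_
        return np.array([v.get(t, UNK) for t in seq.tokens] or [PAD],
                        dtype=np.int64)

    @staticmethod
    def _pad_batch(encoded: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        L = max(len(e) for e in encoded)
        ids = np.zeros((len(encoded), L), dtype=np.int64)
        mask = np.zeros((len(encoded), L))
        for i, e in enumerate(encoded):
            ids[i, :len(e)] = e
            mask[i, :len(e)] = 1.0
        return ids, mask

    # ---- training ---------------------------------------------------------

    def fit(self, train_seqs, y_train, dev_seqs, y_dev):
        spec = self.spec
        y_train = np.asarray(y_train, dtype=float)
        y_dev = np.asarray(y_dev, dtype=int)
        rng = np.random.default_rng(spec.seed)
        drop_rng = np.random.default_rng(spec.seed + 90001)

        if (spec.dev_eval_max is not None
                and len(dev_seqs) > spec.dev_eval_max):
            # stratified cap: keep every dev positive, subsample negatives
            pos = np.flatnonzero(y_dev == 1)
            neg = np.flatnonzero(y_dev == 0)
            budget = max(spec.dev_eval_max - pos.size, 1)
            sub_rng = np.random.default_rng(spec.seed + 70001)
            neg = sub_rng.choice(neg, size=min(budget, neg.size),
                                 replace=False)
            keep = np.sort(np.concatenate([pos, neg]))
            dev_seqs = [dev_seqs[i] for i in keep]
            y_dev = y_dev[keep]

        self._build_vocab(train_seqs)
        enc_train = [self._encode(s) for s in train_seqs]
        idx, weights = rebalance(y_train.astype(int), spec.imbalance_mode, rng)
        enc_train = [enc_train[i] for i in idx]
        y_bal = y_train[idx]
        w_bal = weights

        V = len(self.vocab_)
        self.embedding_ = rng.normal(0, 0.1, size=(V, spec.embed_dim))
        self.embedding_[PAD] = 0.0
        self.params_ = self.net.init_params(rng)
        opt_params = dict(self.params_)
        opt_params["__embedding__"] = self.embedding_
        opt = Adam(opt_params, lr=spec.learning_rate)

        stopper = EarlyStopper(spec.patience, min_epochs=spec.min_epochs)
        best_snapshot = None
        n = len(enc_train)
        for epoch in range(1, spec.max_epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, spec.batch_size):
                batch = order[start:start + spec.batch_size]
                ids, mask = self._pad_batch([enc_train[i] for i in batch])
                X = self.embedding_[ids]
                logit, cache = self.net.forward(
                    self.params_, X, mask, train=True, drop_rng=drop_rng)
                p = 0.5 * (1.0 + np.tanh(0.5 * logit))
                yb, wb = y_bal[batch], w_bal[batch]
                loss = -np.mean(wb * (yb * np.log(p + 1e-12)
                                      + (1 - yb) * np.log(1 - p + 1e-12)))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} "
                        f"(family={spec.family}, batch start={start})")
                dlogit = wb * (p - yb) / len(batch)
                grads, dX = self.net.backward(self.params_, cache, dlogit)
                dE = np.zeros_like(self.embedding_)
                np.add.at(dE, ids, dX[:, :ids.shape[1], :])
                dE[PAD] = 0.0
                grads["__embedding__"] = dE
                opt.step(opt_params, grads)
                self.embedding_[PAD] = 0.0
            bac = self._dev_bac(dev_seqs, y_dev)
            improved = stopper.update(bac)
            if stopper.best_epoch == epoch:
                best_snapshot = ({k: v.copy() for k, v in self.params_.items()},
                                 self.embedding_.copy())
            if not improved:
                break
        self.epochs_trained = stopper.epoch
        self.best_epoch = stopper.best_epoch
        self.best_dev_bac = float(stopper.best_value)
        if best_snapshot is not None:
            self.params_, self.embedding_ = best_snapshot
        return self

    def _dev_bac(self, dev_seqs, y_dev) -> float:
        scores = self.predict_proba(dev_seqs)
        if y_dev.min() == y_dev.max():
            return 0.0
        return confusion_metrics(y_dev, scores, self.spec.threshold).bac

    # ---- inference --------------------------------------------------------

    def predict_proba(self, token_seqs) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("model is not fitted")
        out = np.empty(len(token_seqs))
        bs = max(1, self.spec.batch_size)
        for start in range(0, len(token_seqs), bs):
            chunk = token_seqs[start:start + bs]
            ids, mask = self._pad_batch([self._encode(s) for s in chunk])
            X = self.embedding_[ids]
            logit, _ = self.net.forward(self.params_, X, mask, train=False)
            out[start:start + len(chunk)] = 0.5 * (1.0 + np.tanh(0.5 * logit))
        return out

    # ---- attribution support ---------------------------------------------

    def embed(self, seq: TokenSeq) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Embedded input (L, D), its mask, and the tokens actually seen
        (after any truncation)."""
        if self.params_ is None:
            raise RuntimeError("model is not fitted")
        limit = self._limit()
        if limit is not None:
            seq = truncate(seq, limit)
        ids = self._encode(seq)
        X = self.embedding_[ids]
        return X, np.ones(len(ids)), list(seq.tokens) or ["<pad>"]

    def forward_from_embeddings(self, X: np.ndarray, mask: np.ndarray,
                                output: str = "prob"
                                ) -> tuple[np.ndarray, np.ndarray]:
        """Scores and input-gradients for a batch of embedded documents.

        Returns ``(scores (B,), dscore/dX (B, L, D))`` where the score is
        the sigmoid probability, or the raw logit for ``output='logit'``.
        """
        if self.params_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None, :, :]
            mask = np.asarray(mask)[None, :]
        logit, cache = self.net.forward(self.params_, X, mask, train=False)
        if output == "logit":
            score, dlogit = logit, np.ones_like(logit)
        else:
            p = 0.5 * (1.0 + np.tanh(0.5 * logit))
            score, dlogit = p, p * (1 - p)
        _, dX = self.net.backward(self.params_, cache, dlogit)
        return score, dX[:, :X.shape[1], :]
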