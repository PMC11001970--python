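"""Bag-of-words classifier: token counts into L2 logistic regression.

The vectorizer counts stemmed-token occurrences (vocabulary built on the
training partition only, minimum document frequency 5 by default, no
stop-word removal); the classifier is L2-regularized logistic regression
with the regularization strength selected on development-set balanced
accuracy.  Count features are variance-standardized (scaled by their
training-set standard deviation, not centred) before the ridge penalty
is applied, so the penalty treats rare informative tokens and frequent
filler on an equal footing; the features remain occurrence counts up to
a fixed per-token rescaling.  Coefficient weights are exposed for the
interpretation stage.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression

from ..metrics import confusion_metrics
from .base import ModelSpec, rebalance


class BowVectorizer:
    """Token-count vectorizer over pre-tokenized sequences."""

    def __init__(self, min_df: int = 5):
        self.min_df = min_df
        self.vocabulary_: dict[str, int] = {}

    def fit(self, token_seqs) -> "BowVectorizer":
        df: dict[str, int] = {}
        for seq in token_seqs:
            for tok in set(seq.tokens):
                df[tok] = df.get(tok, 0) + 1
        vocab = sorted(t for t, c in df.items() if c >= self.min_df)
        if not vocab:
            raise ValueError(
                f"empty vocabulary: no token reaches min_df={self.min_df}")
        self.vocabulary_ = {t: i for i, t in enumerate(vocab)}
        return self

    def transform(self, token_seqs) -> sparse.csr_matrix:
        vocab = self.vocabulary_
        indptr, indices, data = [0], [], []
        for seq in token_seqs:
            counts: dict[int, int] = {}
            for tok in seq.tokens:
                j = vocab.get(tok)
                if j is not None:
                    counts[j] = counts.get(j, 0) + 1
            for j in sorted(counts):
                indices.append(j)
                data.append(counts[j])
            indptr.append(len(indices))
        return sparse.csr_matrix(
            (np.asarray(data, dtype=float), indices, indptr),
            shape=(len(token_seqs), len(vocab)))

    @property
    def feature_names(self) -> list[str]:
        return sorted(self.vocabulary_, key=self.vocabulary_.get)


class BowModel:
    """Count features + L2 logistic regression, C tuned on dev BAC."""

    def __init__(self, spec: ModelSpec):
        if spec.family != "bow":
            raise ValueError("BowModel requires a 'bow' spec")
        self.spec = spec
        self.vectorizer = BowVectorizer(min_df=spec.min_df)
        self.classifier_: LogisticRegression | None = None
        self.scale_: np.ndarray | None = None
        self.best_dev_bac: float | None = None
        self.epochs_trained = 0

    def _features(self, token_seqs) -> sparse.csr_matrix:
        X = self.vectorizer.transform(token_seqs)
        if self.scale_ is not None:
            X = X @ sparse.diags(self.scale_)
        return X

    def fit(self, train_seqs, y_train, dev_seqs=None, y_dev=None):
        y_train = np.asarray(y_train, dtype=int)
        self.vectorizer.fit(train_seqs)
        Xraw = self.vectorizer.transform(train_seqs)
        if self.spec.scale_counts:
            var = np.asarray(Xraw.power(2).mean(axis=0)).ravel() - \
                np.asarray(Xraw.mean(axis=0)).ravel() ** 2
            sd = np.sqrt(np.maximum(var, 0.0))
            self.scale_ = np.where(sd > 0, 1.0 / np.maximum(sd, 1e-12), 1.0)
        Xtr = self._features(train_seqs)
        rng = np.random.default_rng(self.spec.seed)
        idx, weights = rebalance(y_train, self.spec.imbalance_mode, rng)
        Xtr, ytr, wtr = Xtr[idx], y_train[idx], weights
        best = (None, -np.inf)
        for C in self.spec.C_grid:
            clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000)
            clf.fit(Xtr, ytr, sample_weight=wtr)
            ydv = None if y_dev is None else np.asarray(y_dev, dtype=int)
            if (dev_seqs is not None and len(self.spec.C_grid) > 1
                    and ydv is not None and ydv.min() != ydv.max()):
                scores = clf.predict_proba(self._features(dev_seqs))[:, 1]
                bac = confusion_metrics(ydv, scores, self.spec.threshold).bac
            else:
                bac = 0.0
            if bac > best[1] or best[0] is None:
                best = (clf, bac)
        self.classifier_, self.best_dev_bac = best
        return self

    def predict_proba(self, token_seqs) -> np.ndarray:
        if self.classifier_ is None:
            raise RuntimeError("model is not fitted")
        return self.classifier_.predict_proba(
            self._features(token_seqs))[:, 1]

    def coefficients(self) -> dict[str, float]:
        """Token -> logistic-regression coefficient."""
        if self.classifier_ is None:
            raise RuntimeError("model is not fitted")
        return dict(zip(self.vectorizer.feature_names,
                        self.classifier_.coef_[0]))
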