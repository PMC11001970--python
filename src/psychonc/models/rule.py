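"""Rule-based comparator.

Predicts a patient will see a psychiatrist iff their consultation
contains the stemmed token "psychiatrist", and a counsellor iff it
contains "counsel" — i.e. the trivial strategy of flagging documents
where the oncologist already names the discipline.  Consumes the same
bag-of-words dialect as the BoW model.
"""

from __future__ import annotations

import numpy as np

from .base import ModelSpec

RULE_TOKENS = {"psychiatrist": "psychiatrist", "counsellor": "counsel"}


class RuleModel:
    """Deterministic token-presence classifier."""

    def __init__(self, spec: ModelSpec):
        if spec.family != "rule":
            raise ValueError("RuleModel requires a 'rule' spec")
        self.spec = spec
        self.trigger = RULE_TOKENS[spec.target]
        self.best_dev_bac: float | None = None
        self.epochs_trained = 0

    def fit(self, train_seqs, y_train, dev_seqs=None, y_dev=None):
        return self  # nothing to learn

    def predict_proba(self, token_seqs) -> np.ndarray:
        return np.array(
            [1.0 if self.trigger in seq.tokens else 0.0
             for seq in token_seqs])
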