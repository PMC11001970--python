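"""Model zoo: rule-based comparator, BoW, CNN, BiLSTM, transformer slot.

Every family exposes ``fit(train_seqs, y_train, dev_seqs, y_dev)`` and
``predict_proba(token_seqs) -> scores in [0, 1]``, so the evaluation
protocol is family-agnostic.
"""

from .base import (FAMILIES, FAMILY_DIALECT, IMBALANCE_MODES,
                   TRANSFORMER_TOKEN_LIMITS, EarlyStopper, ModelSpec,
                   rebalance)
from .bow import BowModel, BowVectorizer
from .io import load_model, save_model
from .nets import Adam, BiLSTMNet, CNNNet, MeanPoolNet, TransformerNet
from .rule import RULE_TOKENS, RuleModel
from .trainer import SequenceModel

__all__ = [
    "FAMILIES", "FAMILY_DIALECT", "IMBALANCE_MODES",
    "TRANSFORMER_TOKEN_LIMITS", "EarlyStopper", "ModelSpec", "rebalance",
    "BowModel", "BowVectorizer", "RuleModel", "RULE_TOKENS",
    "SequenceModel", "Adam", "BiLSTMNet", "CNNNet", "MeanPoolNet",
    "TransformerNet", "make_model", "save_model", "load_model",
]

_SEQUENCE_FAMILIES = ("cnn", "lstm", "transformer", "meanpool")


def make_model(spec: ModelSpec):
    """Instantiate the model for a spec; raises for unknown families."""
    if spec.family == "rule":
        return RuleModel(spec)
    if spec.family == "bow":
        return BowModel(spec)
    if spec.family in _SEQUENCE_FAMILIES:
        return SequenceModel(spec)
    raise ValueError(f"unimplemented model family {spec.family!r}")
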