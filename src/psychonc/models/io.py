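"""Model artifact serialization.

A trained model is written as a versioned ``.npz`` of arrays plus a
JSON sidecar recording the spec, a vocabulary hash, the best dev BAC
and the epochs trained — enough to verify provenance before loading.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .base import ModelSpec
from .bow import BowModel
from .trainer import SequenceModel

FORMAT_VERSION = 1


def _vocab_hash(tokens) -> str:
    blob = "\x00".join(tokens).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sidecar(model, vocab_tokens) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "spec": asdict(model.spec),
        "vocabulary_hash": _vocab_hash(vocab_tokens),
        "best_dev_bac": model.best_dev_bac,
        "epochs_trained": model.epochs_trained,
    }


def save_model(model, path) -> None:
    """Write ``<path>.npz`` and ``<path>.json`` for a fitted model."""
    path = Path(path)
    if isinstance(model, BowModel):
        if model.classifier_ is None:
            raise RuntimeError("model is not fitted")
        vocab = model.vectorizer.feature_names
        arrays = {
            "kind": np.array("bow"),
            "vocabulary": np.array(vocab, dtype=object),
            "coef": model.classifier_.coef_,
            "intercept": model.classifier_.intercept_,
            "C": np.array(model.classifier_.C),
            "scale": (model.scale_ if model.scale_ is not None
                      else np.array([])),
        }
    elif isinstance(model, SequenceModel):
        if model.params_ is None:
            raise RuntimeError("model is not fitted")
        vocab = sorted(model.vocab_, key=model.vocab_.get)
        arrays = {"kind": np.array("sequence"),
                  "vocabulary": np.array(vocab, dtype=object),
                  "embedding": model.embedding_}
        arrays.update({f"param_{k}": v for k, v in model.params_.items()})
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(
        json.dumps(_sidecar(model, vocab), indent=2, sort_keys=True))


def load_model(path):
    """Load a model written by :func:`save_model`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar["format_version"] != FORMAT_VERSION:
        raise ValueError(
            f"unsupported artifact format {sidecar['format_version']}")
    spec_d = dict(sidecar["spec"])
    for key in ("C_grid", "conv_widths"):
        if key in spec_d and spec_d[key] is not None:
            spec_d[key] = tuple(spec_d[key])
    spec = ModelSpec(**spec_d)
    data = np.load(path.with_suffix(".npz"), allow_pickle=True)
    vocab = [str(t) for t in data["vocabulary"]]
    if _vocab_hash(vocab) != sidecar["vocabulary_hash"]:
        raise ValueError("vocabulary hash mismatch; artifact corrupted")
    kind = str(data["kind"])
    if kind == "bow":
        from sklearn.linear_model import LogisticRegression

        model = BowModel(spec)
        model.vectorizer.vocabulary_ = {t: i for i, t in enumerate(vocab)}
        clf = LogisticRegression(C=float(data["C"]))
        clf.coef_ = data["coef"]
        clf.intercept_ = data["intercept"]
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = clf.coef_.shape[1]
        model.classifier_ = clf
        scale = data["scale"]
        model.scale_ = scale if scale.size else None
    else:
        model = SequenceModel(spec)
        model.vocab_ = {t: i for i, t in enumerate(vocab)}
        model.embedding_ = data["embedding"]
        model.params_ = {k[len("param_"):]: data[k]
                         for k in data.files if k.startswith("param_")}
    model.best_dev_bac = sidecar["best_dev_bac"]
    model.epochs_trained = sidecar["epochs_trained"]
    return model
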