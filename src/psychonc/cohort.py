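"""Cohort exclusions, index-document selection, labels, tokenization, splits.

Mirrors the study's data preparation: drop patients who started cancer
care more than once, require a medical/radiation oncology consultation
within 180 days of diagnosis, take the oncology document closest to
diagnosis as the sole model input, and label a patient positive when a
psychiatry (or counselling) document appears within the 365 days *after*
the index document.  Window conventions are closed on the right:
eligibility uses day offsets in [0, 180], outcomes use offsets in
(0, 365] — a contact on the same day as the index document does not
count as "after" it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (ONCOLOGY_SPECIALTIES, TARGET_SPECIALTY, TARGETS,
                        ConsultDocument, PatientRecord, Registry)
from .stemmer import porter_stem
from .subword import DEFAULT_SUBWORD_VOCAB, SubwordVocab

__all__ = [
    "apply_exclusions", "select_index_document", "assign_labels",
    "tokenize", "split_ids", "truncate", "TokenSeq", "LabelledDataset",
]

DIALECTS = ("bow", "neural", "transformer")
ELIGIBILITY_WINDOW_DAYS = 180
OUTCOME_WINDOW_DAYS = 365


@dataclass(frozen=True)
class TokenSeq:
    """An ordered token sequence in one preprocessing dialect."""

    dialect: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class LabelledItem:
    doc_id: str
    patient_id: str
    text: str
    label: int


@dataclass
class LabelledDataset:
    """(document, label) pairs for one target with a train/dev/test split."""

    target: str
    items: list[LabelledItem]
    partition: dict[str, str] = field(default_factory=dict)

    def subset(self, part: str) -> list[LabelledItem]:
        return [it for it in self.items if self.partition.get(it.doc_id) == part]

    def labels(self, part: str | None = None) -> np.ndarray:
        items = self.items if part is None else self.subset(part)
        return np.array([it.label for it in items], dtype=int)

    def tokens(self, dialect: str, part: str | None = None,
               subword_vocab: SubwordVocab | None = None) -> list[TokenSeq]:
        items = self.items if part is None else self.subset(part)
        return [tokenize(it.text, dialect, subword_vocab=subword_vocab)
                for it in items]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([
            {"doc_id": it.doc_id, "patient_id": it.patient_id,
             "target": self.target, "label": it.label,
             "partition": self.partition.get(it.doc_id, "")}
            for it in self.items])


# ---------------------------------------------------------------------------
# cohort filters


def _has_valid_consult(patient: PatientRecord,
                       window: int = ELIGIBILITY_WINDOW_DAYS) -> bool:
    return any(
        0 <= d.day - patient.diagnosis_day <= window
        for d in patient.documents_of(*ONCOLOGY_SPECIALTIES))


def apply_exclusions(registry: Registry | list[PatientRecord]
                     ) -> list[PatientRecord]:
    """Drop multi-start patients, then those without a valid consultation.

    Order-stable and idempotent.
    """
    patients = registry.patients if isinstance(registry, Registry) else registry
    return [p for p in patients
            if not p.multi_start and _has_valid_consult(p)]


def select_index_document(patient: PatientRecord) -> ConsultDocument:
    """The oncology document closest to diagnosis.

    Eligibility for *retention* requires an in-window consult, but the
    index document itself is simply the oncology document minimizing
    |day - diagnosis| (it may predate diagnosis).  Ties break toward the
    earlier day, then the lexicographically smaller doc_id.
    """
    candidates = patient.documents_of(*ONCOLOGY_SPECIALTIES)
    if not candidates:
        raise ValueError(
            f"patient {patient.patient_id} has no oncology document; "
            "apply_exclusions must run first")
    return min(candidates, key=lambda d: (abs(d.day - patient.diagnosis_day),
                                          d.day, d.doc_id))


def assign_labels(cohort: list[PatientRecord], target: str,
                  window_days: int = OUTCOME_WINDOW_DAYS) -> LabelledDataset:
    """Label 1 iff a target-discipline document falls in (0, window] days
    after the index document."""
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    specialty = TARGET_SPECIALTY[target]
    items = []
    for p in cohort:
        index_doc = select_index_document(p)
        label = int(any(
            0 < d.day - index_doc.day <= window_days
            for d in p.documents_of(specialty)))
        items.append(LabelledItem(doc_id=index_doc.doc_id,
                                  patient_id=p.patient_id,
                                  text=index_doc.text, label=label))
    return LabelledDataset(target=target, items=items)


# ---------------------------------------------------------------------------
# tokenization dialects

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def _word_tokens(text: str) -> list[str]:
    out = []
    for chunk in text.lower().split():
        w = _NON_ALNUM.sub("", chunk)
        if w:
            out.append(w)
    return out


def tokenize(text: str, dialect: str,
             subword_vocab: SubwordVocab | None = None) -> TokenSeq:
    """Tokenize text in one of the three preprocessing dialects.

    bow: lowercase, punctuation stripped, suffix-stripping stemming.
    neural: lowercase word tokens, no stemming.
    transformer: greedy longest-match subword pieces over a WordPiece-style
    vocabulary (corpus-trained via :class:`SubwordVocab`, or a packaged
    default).  Total on arbitrary printable text; empty text gives an
    empty sequence.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {DIALECTS}")
    words = _word_tokens(text)
    if dialect == "bow":
        toks = [porter_stem(w) for w in words]
    elif dialect == "neural":
        toks = words
    else:
        vocab = subword_vocab or DEFAULT_SUBWORD_VOCAB
        toks = [piece for w in words for piece in vocab.encode_word(w)]
    return TokenSeq(dialect=dialect, tokens=tuple(toks))


def truncate(seq: TokenSeq, max_tokens: int) -> TokenSeq:
    """Keep the first ``max_tokens`` tokens; the tail is trimmed off."""
    if max_tokens < 1:
        raise ValueError(f"max_tokens must be >= 1, got {max_tokens}")
    if len(seq.tokens) <= max_tokens:
        return seq
    return TokenSeq(dialect=seq.dialect, tokens=seq.tokens[:max_tokens])


# ---------------------------------------------------------------------------
# splitting


def split_ids(ids: list[str], fractions=(0.7, 0.1, 0.2),
              rng: np.random.Generator | int | None = 0) -> dict[str, str]:
    """Random train/dev/test partition with largest-remainder rounding.

    Partition sizes are floor(n * f) with leftover units assigned by
    descending fractional remainder (ties toward the earlier part), so
    n=10 at (0.7, 0.1, 0.2) gives sizes (7, 1, 2) exactly.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if len(fractions) != 3:
        raise ValueError("expected exactly (train, dev, test) fractions")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(ids)
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainder = n - sum(sizes)
    order = sorted(range(3), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    perm = rng.permutation(n)
    names = ("train", "dev", "test")
    out: dict[str, str] = {}
    start = 0
    for name, size in zip(names, sizes):
        for j in perm[start:start + size]:
            out[ids[j]] = name
        start += size
    return out
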