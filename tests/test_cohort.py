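"""Cohort preparation: exclusions, index selection, labels, tokens, splits."""

import string

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psychonc import (apply_exclusions, assign_labels, select_index_document,
                      split_ids, tokenize, truncate)
from psychonc.cohort import TokenSeq
from psychonc.datatypes import Registry

from conftest import event_doc, make_patient, onc_doc


# ---------------------------------------------------------------------------
# exclusions


def test_exclusion_filter_small_arithmetic():
    patients = []
    for i in range(10):
        docs = [onc_doc(f"D{i}", f"P{i}", day=100 + 10)]
        patients.append(make_patient(f"P{i}", diagnosis_day=100,
                                     multi_start=(i < 2), docs=docs))
    # two multi-start; one more with only an out-of-window consult
    patients[5].documents = [onc_doc("D5", "P5", day=100 + 181)]
    kept = apply_exclusions(patients)
    assert [p.patient_id for p in kept] == [
        "P2", "P3", "P4", "P6", "P7", "P8", "P9"]


def test_consult_at_180_days_is_valid_at_181_excluded():
    ok = make_patient("A", 0, docs=[onc_doc("d", "A", day=180)])
    out = make_patient("B", 0, docs=[onc_doc("d", "B", day=181)])
    assert [p.patient_id for p in apply_exclusions([ok, out])] == ["A"]


def test_exclusions_idempotent(small_registry):
    once = apply_exclusions(small_registry)
    twice = apply_exclusions(once)
    assert [p.patient_id for p in once] == [p.patient_id for p in twice]


def test_non_oncology_documents_do_not_qualify():
    p = make_patient("A", 0, docs=[event_doc("d", "A", 10, "psychiatry")])
    assert apply_exclusions([p]) == []


# ---------------------------------------------------------------------------
# index document


def test_index_document_closest_to_diagnosis():
    p = make_patient("A", 100, docs=[onc_doc("d1", "A", 140),
                                     onc_doc("d2", "A", 110)])
    assert select_index_document(p).doc_id == "d2"


def test_index_tie_breaks_earlier_day_then_doc_id():
    # days -5 and +5 from diagnosis: equal distance, earlier day wins
    p = make_patient("A", 100, docs=[onc_doc("d1", "A", 105),
                                     onc_doc("d2", "A", 95)])
    assert select_index_document(p).doc_id == "d2"
    # equal day: lexicographic doc_id
    p2 = make_patient("B", 100, docs=[onc_doc("db", "B", 110),
                                      onc_doc("da", "B", 110)])
    assert select_index_document(p2).doc_id == "da"


def test_single_document_is_its_own_index():
    p = make_patient("A", 100, docs=[onc_doc("d", "A", 150)])
    assert select_index_document(p).doc_id == "d"


def test_index_requires_oncology_document():
    p = make_patient("A", 100,
                     docs=[event_doc("e", "A", 110, "psychiatry")])
    with pytest.raises(ValueError, match="no oncology"):
        select_index_document(p)


# ---------------------------------------------------------------------------
# labels


def _cohort_with_event(offset):
    docs = [onc_doc("idx", "A", day=50)]
    if offset is not None:
        docs.append(event_doc("ev", "A", day=50 + offset, specialty="psychiatry"))
    return [make_patient("A", diagnosis_day=50, docs=docs)]


@pytest.mark.parametrize("offset,label", [
    (100, 1),   # inside the 12-month window
    (365, 1),   # right edge is closed
    (400, 0),   # outside
    (0, 0),     # same day as index is not "after"
    (None, 0),  # no contact at all
])
def test_label_window_boundaries(offset, label):
    ds = assign_labels(_cohort_with_event(offset), "psychiatrist")
    assert ds.items[0].label == label


def test_unknown_target_rejected():
    with pytest.raises(ValueError, match="unknown target"):
        assign_labels([], "surgeon")


def test_labels_monotone_in_window(small_registry):
    cohort = apply_exclusions(small_registry)
    wide = assign_labels(cohort, "counsellor", window_days=365)
    narrow = assign_labels(cohort, "counsellor", window_days=180)
    pos_wide = {it.doc_id for it in wide.items if it.label}
    pos_narrow = {it.doc_id for it in narrow.items if it.label}
    assert pos_narrow <= pos_wide


# ---------------------------------------------------------------------------
# tokenization


@pytest.mark.parametrize("text,dialect,expected", [
    ("depression", "bow", ("depress",)),
    ("anxieties", "bow", ("anxieti",)),
    ("Counselling", "bow", ("counsel",)),
    ("Grade 1 tumour, left side.", "bow",
     ("grade", "1", "tumour", "left", "side")),
    ("Weight loss of 5 kg", "neural", ("weight", "loss", "of", "5", "kg")),
])
def test_tokenize_examples(text, dialect, expected):
    assert tokenize(text, dialect).tokens == expected


def test_transformer_dialect_marks_continuations():
    toks = tokenize("radiotherapy unusualwordxq", "transformer").tokens
    assert toks[0] == "radiotherapy"
    assert any(t.startswith("##") for t in toks[1:])


def test_tokenize_unknown_dialect():
    with pytest.raises(ValueError, match="dialect"):
        tokenize("text", "charlevel")


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.text(alphabet=string.printable, max_size=200),
       st.sampled_from(["bow", "neural", "transformer"]))
def test_tokenization_total_and_deterministic(text, dialect):
    seq = tokenize(text, dialect)
    assert seq.tokens == tokenize(text, dialect).tokens
    assert all(t == t.lower() for t in seq.tokens)


def test_empty_text_empty_sequence():
    for dialect in ("bow", "neural", "transformer"):
        assert tokenize("", dialect).tokens == ()


# ---------------------------------------------------------------------------
# truncation


def test_truncate_keeps_prefix():
    seq = TokenSeq("neural", tuple(f"t{i}" for i in range(1600)))
    out = truncate(seq, 1500)
    assert len(out) == 1500 and out.tokens[:3] == ("t0", "t1", "t2")
    assert truncate(seq, 5000).tokens == seq.tokens
    assert truncate(seq, 1).tokens == ("t0",)
    with pytest.raises(ValueError):
        truncate(seq, 0)


# ---------------------------------------------------------------------------
# splitting


def test_split_exact_sizes_n10():
    part = split_ids([str(i) for i in range(10)])
    sizes = {p: sum(1 for v in part.values() if v == p)
             for p in ("train", "dev", "test")}
    assert sizes == {"train": 7, "dev": 1, "test": 2}


def test_split_largest_remainder_cohort_size():
    """At the study cohort size the 20% test split is exactly 9,525."""
    ids = [str(i) for i in range(47_625)]
    part = split_ids(ids, rng=3)
    assert sum(1 for v in part.values() if v == "test") == 9_525
    assert sum(1 for v in part.values() if v == "dev") == 4_762
    assert sum(1 for v in part.values() if v == "train") == 33_338


def test_split_is_partition_and_deterministic():
    ids = [f"id{i}" for i in range(103)]
    a = split_ids(ids, rng=5)
    b = split_ids(ids, rng=5)
    assert a == b
    assert set(a) == set(ids)  # union = cohort, no id lost or duplicated


def test_split_rejects_bad_fractions():
    with pytest.raises(ValueError, match="sum to 1"):
        split_ids(["a", "b"], fractions=(0.5, 0.2, 0.2))
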