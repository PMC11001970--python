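"""Shared fixtures: small synthetic registries and labelled datasets.

Everything is generated programmatically at collection time; no data
files ship with the tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from psychonc import (apply_exclusions, assign_labels, generate_registry,
                      split_ids)
from psychonc.config import GeneratorConfig
from psychonc.datatypes import ConsultDocument, PatientRecord
from psychonc.presets import ig_demo_config


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A quick, rendered corpus with a moderate planted signal."""
    return ig_demo_config()


@pytest.fixture(scope="session")
def small_registry(small_config):
    return generate_registry(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_registry):
    ds = assign_labels(apply_exclusions(small_registry), "psychiatrist")
    ds.partition = split_ids([it.doc_id for it in ds.items], rng=0)
    return ds


def make_patient(patient_id="P1", diagnosis_day=100, multi_start=False,
                 docs=()):
    """Hand-built patient record for boundary tests."""
    return PatientRecord(
        patient_id=patient_id, diagnosis_day=diagnosis_day, age=60.0,
        sex="female", stage="II", multi_start=multi_start,
        documents=list(docs))


def onc_doc(doc_id, patient_id, day, text="Consultation note.",
            specialty="medical_oncology"):
    return ConsultDocument(doc_id=doc_id, patient_id=patient_id,
                           specialty=specialty, day=day, text=text)


def event_doc(doc_id, patient_id, day, specialty):
    return ConsultDocument(doc_id=doc_id, patient_id=patient_id,
                           specialty=specialty, day=day, text="Seen.")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
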