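"""Shared domain records: patients, consultation documents, registries.

All dates are integer day offsets from a fixed study epoch (day 0), which
sidesteps calendar and timezone ambiguity.  A registry bundles the patient
table with every document event (oncology consultations plus any later
psychiatry / counselling contacts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

ONCOLOGY_SPECIALTIES = ("medical_oncology", "radiation_oncology")
SPECIALTIES = ONCOLOGY_SPECIALTIES + ("psychiatry", "counselling")
TARGETS = ("psychiatrist", "counsellor")

#: discipline of the document event that defines each outcome
TARGET_SPECIALTY = {"psychiatrist": "psychiatry", "counsellor": "counselling"}


@dataclass(frozen=True)
class ConsultDocument:
    """One clinical document: text, authoring specialty, creation day."""

    doc_id: str
    patient_id: str
    specialty: str
    day: int
    text: str

    def __post_init__(self) -> None:
        if self.specialty not in SPECIALTIES:
            raise ValueError(f"unknown specialty: {self.specialty!r}")
        if self.specialty in ONCOLOGY_SPECIALTIES and not self.text:
            raise ValueError("oncology documents must have non-empty text")


@dataclass
class PatientRecord:
    """One patient with their document events."""

    patient_id: str
    diagnosis_day: int
    age: float
    sex: str
    stage: str
    multi_start: bool = False
    documents: list[ConsultDocument] = field(default_factory=list)

    def documents_of(self, *specialties: str) -> list[ConsultDocument]:
        return [d for d in self.documents if d.specialty in specialties]


@dataclass
class Registry:
    """Patient table plus all document events, as generated or ingested."""

    patients: list[PatientRecord]

    def __post_init__(self) -> None:
        ids = {p.patient_id for p in self.patients}
        if len(ids) != len(self.patients):
            raise ValueError("duplicate patient_id in registry")
        for p in self.patients:
            for d in p.documents:
                if d.patient_id != p.patient_id:
                    raise ValueError(
                        f"document {d.doc_id} attached to wrong patient"
                    )

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def documents(self) -> list[ConsultDocument]:
        return [d for p in self.patients for d in p.documents]

    # ---- external formats -------------------------------------------------

    def corpus_jsonl(self) -> str:
        """All documents, one JSON object per line."""
        lines = []
        for p in self.patients:
            for d in p.documents:
                lines.append(json.dumps(
                    {"doc_id": d.doc_id, "patient_id": d.patient_id,
                     "specialty": d.specialty, "day": d.day, "text": d.text},
                    ensure_ascii=False, sort_keys=True))
        return "\n".join(lines) + ("\n" if lines else "")

    def registry_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            psych = [d.day for d in p.documents if d.specialty == "psychiatry"]
            coun = [d.day for d in p.documents if d.specialty == "counselling"]
            rows.append({
                "patient_id": p.patient_id,
                "age": p.age, "sex": p.sex, "stage": p.stage,
                "diagnosis_day": p.diagnosis_day,
                "multi_start": int(p.multi_start),
                "psych_day": min(psych) if psych else None,
                "counsel_day": min(coun) if coun else None,
            })
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "corpus.jsonl").write_text(self.corpus_jsonl())
        self.registry_frame().to_csv(out / "registry.csv", index=False)

    @classmethod
    def read(cls, indir) -> "Registry":
        from pathlib import Path

        ind = Path(indir)
        reg = pd.read_csv(ind / "registry.csv", dtype={"patient_id": str})
        docs_by_patient: dict[str, list[ConsultDocument]] = {}
        with open(ind / "corpus.jsonl") as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                doc = ConsultDocument(
                    doc_id=str(obj["doc_id"]),
                    patient_id=str(obj["patient_id"]),
                    specialty=obj["specialty"], day=int(obj["day"]),
                    text=obj["text"])
                docs_by_patient.setdefault(doc.patient_id, []).append(doc)
        patients = []
        for row in reg.itertuples(index=False):
            patients.append(PatientRecord(
                patient_id=row.patient_id,
                diagnosis_day=int(row.diagnosis_day),
                age=float(row.age), sex=row.sex, stage=str(row.stage),
                multi_start=bool(row.multi_start),
                documents=docs_by_patient.get(row.patient_id, []),
            ))
        return cls(patients)
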