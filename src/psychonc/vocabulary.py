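"""Filler vocabulary for synthetic consultation documents.

A packaged list of clinical and common tokens used as the background word
distribution when rendering documents.  The list deliberately contains the
surface forms that the interpretation stages later look for (mental-health
terms, place names, numerals), plus the six canonical section headers of a
consultation note.  Sampling weights follow a Zipf-like decay so a few
tokens are common and most are rare, as in real clinical text.

The rule-based comparator's trigger forms ("psychiatrist",
"counselling" and spelling variants) are deliberately *excluded* from
the filler list: their appearance in a document is controlled solely by
the configured signal emissions, mirroring how rare and informative they
are in real consultations.
"""

from __future__ import annotations

import numpy as np

SECTION_HEADERS = (
    "IDENTIFYING INFORMATION:",
    "HISTORY OF PRESENTATION:",
    "MEDICAL AND OTHER HISTORIES:",
    "PHYSICAL EXAMINATION:",
    "IMPRESSION AND ASSESSMENT:",
    "RECOMMENDATION AND PLAN:",
)

#: default fraction of the filler-token budget given to each section
SECTION_WEIGHTS = (0.08, 0.22, 0.25, 0.15, 0.15, 0.15)

_COMMON = """
the a an and or of to in with for on at by from as is was were has had have
not no this that she he her his they their patient who which will would been
be are after before today also very some more most other about over under
between during since than when then there out up down per day week month year
old new well left right both
""".split()

_CLINICAL = """
history presentation examination impression assessment recommendation plan
identifying information medical surgical family social diagnosis diagnosed
consultation referral referred clinic oncology oncologist radiation medical
chemotherapy radiotherapy treatment therapy cycle cycles dose doses fraction
fractions adjuvant neoadjuvant palliative curative systemic hormonal
carcinoma adenocarcinoma tumor tumour mass lesion nodule malignant benign
metastatic metastases stage grade biopsy pathology histology margins node
nodes lymph breast lung colon rectal prostate ovarian cervical gastric
pancreatic melanoma lymphoma leukemia myeloma sarcoma glioblastoma squamous
cell ductal lobular invasive situ receptor positive negative marker markers
mammogram ultrasound imaging scan scans ct mri pet xray ray bone marrow
staging workup bloodwork baseline hemoglobin platelets neutrophils counts
creatinine liver renal cardiac pulmonary performance status ecog karnofsky
symptoms symptom pain discomfort fatigue nausea vomiting appetite weight
loss gain fever chills night sweats cough dyspnea shortness breath edema
peripheral swelling numbness tingling neuropathy constipation diarrhea
insomnia sleep energy mood anxiety anxious anxieties worried worry distress
distressed depression depressed depressive tearful crying hopeless
helpless suicidal suicide ideation panic stress stressed stressor coping
psychiatry psychologist psychosocial support supportive grief adjustment
fear fears
medications medication allergies allergy penicillin codeine tylenol
acetaminophen ibuprofen morphine hydromorphone oxycodone fentanyl
dexamethasone prednisone ondansetron metoclopramide lorazepam zopiclone
citalopram sertraline venlafaxine trazodone mirtazapine gabapentin
tamoxifen letrozole anastrozole cisplatin carboplatin paclitaxel docetaxel
doxorubicin cyclophosphamide fluorouracil capecitabine gemcitabine
etoposide vincristine rituximab trastuzumab pembrolizumab nivolumab
hypertension diabetes hyperlipidemia hypothyroidism asthma copd arthritis
reflux anemia atrial fibrillation coronary artery disease stroke ulcer
appendectomy cholecystectomy hysterectomy mastectomy lumpectomy resection
colonoscopy gastroscopy tonsillectomy hernia repair cesarean
smoker smoking nonsmoker cigarettes pack packs quit alcohol drinks wine
beer spirits marijuana cannabis substance recreational drugs
married divorced widowed single partner spouse husband wife children
daughter son grandchildren mother father sister brother aunt uncle
grandmother grandfather maternal paternal cousin niece nephew
retired retiree retirement works working worked work unemployed disability
teacher nurse driver labourer manager clerk farmer fisherman logger
accountant engineer homemaker occupation employment financial finances
income housing transportation lives alone apartment house home community
vancouver victoria kelowna surrey abbotsford prince george kamloops nanaimo
richmond burnaby coquitlam langley vernon penticton courtenay cranbrook
terrace columbia british rural urban island northern interior coastal
petrov
examination reveals revealed alert oriented distress acute appears
appearance pleasant cooperative thin cachectic obese vitals blood pressure
pulse rate respiratory temperature saturation afebrile head neck chest
heart sounds murmur lungs clear auscultation bilaterally entry crackles
wheeze abdomen soft nontender tender distended bowel organomegaly
hepatomegaly splenomegaly extremities pitting calf neurological cranial
nerves intact motor sensory reflexes gait skin rash lesions mucosa oral
cavity thyroid masses palpable supraclavicular axillary inguinal
discussed discussion options risks benefits side effects consent obtained
questions answered agreeable follow followup arrange arranged booked
appointment review reviewed refer referral dietitian physiotherapy
pharmacy homecare hospice team conference tumor board consider considered
recommend recommended proceed start starting commence continue monitor
surveillance repeat reassess return visit weeks months
noticed noted reports reported denies endorses describes states feels
finding findings significant unremarkable stable progressive improved
worsened resolved ongoing intermittent occasional persistent chronic
mild moderate severe slightly approximately roughly nearly
menarche menopause menopausal premenopausal gynecological menstrual period
pregnancies births gravida para breastfeeding mammography
port cath insertion picc line placement
memory concentration difficulty word finding
grandparents trauma bereavement loss widower caregiver burden
thanks seeing together regarding copy dictated transcribed
""".split()

_NUMERALS = [str(n) for n in range(0, 21)] + [
    "25", "30", "40", "50", "60", "75", "80", "90", "100", "150", "200",
    "250", "300", "500", "1000", "2011", "2016",
]


def _build() -> list[str]:
    seen: dict[str, None] = {}
    for w in _COMMON + _CLINICAL + _NUMERALS:
        seen.setdefault(w, None)
    return list(seen)


#: the packaged filler vocabulary, order-stable
FILLER_VOCABULARY: tuple[str, ...] = tuple(_build())


def filler_weights(n: int | None = None) -> np.ndarray:
    """Zipf-like sampling weights over the filler vocabulary."""
    n = len(FILLER_VOCABULARY) if n is None else n
    ranks = np.arange(1, n + 1, dtype=float)
    w = 1.0 / (ranks + 20.0)
    return w / w.sum()
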