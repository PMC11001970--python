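"""Synthetic-corpus generator: calibration, determinism, structure."""

import numpy as np
import pytest

from psychonc import generate_registry, render_document, sample_patient
from psychonc.config import ConfigError, GeneratorConfig, SignalToken
from psychonc.corpus import label_probability, sample_emissions, solve_intercept
from psychonc.vocabulary import SECTION_HEADERS


def test_invalid_config_names_offending_field():
    with pytest.raises(ConfigError, match="p_female"):
        GeneratorConfig(p_female=1.5).validate()
    with pytest.raises(ConfigError, match="doc_length_mean"):
        GeneratorConfig(doc_length_mean=-3).validate()
    with pytest.raises(ConfigError, match="stage_probs"):
        GeneratorConfig(stage_probs=(("I", 0.5), ("II", 0.2))).validate()
    with pytest.raises(ConfigError, match="emit_base"):
        GeneratorConfig(signal_tokens=(
            SignalToken("x", emit_base=1.2),)).validate()


def test_degenerate_probabilities(rng):
    cfg = GeneratorConfig(p_female=1.0)
    assert all(sample_patient(cfg, rng).sex == "female" for _ in range(50))
    cfg = GeneratorConfig(stage_probs=(("unknown", 1.0),))
    assert all(sample_patient(cfg, rng).stage == "unknown"
               for _ in range(50))


def test_age_calibration_against_study_mean(rng):
    """Empirical mean age over many draws sits within 3 SE of 64.9."""
    cfg = GeneratorConfig()
    ages = np.array([sample_patient(cfg, rng).age for _ in range(50_000)])
    se = cfg.age_sd / np.sqrt(ages.size)
    assert abs(ages.mean() - 64.9) < 3 * se + 0.05  # +truncation-at-18 bias


def test_document_sections_in_order_and_token_budget(rng):
    cfg = GeneratorConfig(doc_length_mean=400, doc_length_sd=80, seed=3)
    profile = sample_patient(cfg, rng)
    doc = render_document(profile, cfg, rng)
    pos = [doc.text.find(h) for h in SECTION_HEADERS]
    assert all(p >= 0 for p in pos), "all six sections present"
    assert pos == sorted(pos), "sections appear in canonical order"


def test_mean_token_count_matches_configured_length():
    """Whitespace token count is calibrated to the configured mean."""
    cfg = GeneratorConfig(n_patients=2500, seed=9, p_no_valid_consult=0.0,
                          p_multi_start=0.0)
    reg = generate_registry(cfg)
    lengths = [len(d.text.split()) for p in reg.patients
               for d in p.documents if d.specialty.endswith("oncology")]
    se = cfg.doc_length_sd / np.sqrt(len(lengths))
    assert abs(np.mean(lengths) - cfg.doc_length_mean) < 3 * se + 0.5


def test_forced_emission_places_token(rng):
    cfg = GeneratorConfig(signal_tokens=(
        SignalToken("depression", effect_psych=5.0, emit_base=1.0),))
    profile = sample_patient(cfg, rng)
    doc = render_document(profile, cfg, rng)
    assert "depression" in doc.text.lower()


def test_same_seed_byte_identical_registries():
    cfg = GeneratorConfig(n_patients=120, seed=77)
    a, b = generate_registry(cfg), generate_registry(cfg)
    assert a.corpus_jsonl() == b.corpus_jsonl()
    assert a.registry_frame().to_csv() == b.registry_frame().to_csv()


def test_empty_registry_allowed():
    assert len(generate_registry(GeneratorConfig(n_patients=0))) == 0


def test_exact_exclusion_counts_plant_exactly():
    cfg = GeneratorConfig(n_patients=1000, n_multi_start=50,
                          n_no_valid_consult=100, seed=1)
    reg = generate_registry(cfg, render=False)
    n_multi = sum(p.multi_start for p in reg.patients)
    assert n_multi == 50


def test_prevalence_calibration_among_documented_patients():
    """Positive fraction among patients holding an index consultation
    converges to the configured prevalence (3-SE band)."""
    cfg = GeneratorConfig(n_patients=50_000, seed=21)
    reg = generate_registry(cfg, render=False)
    with_doc = [p for p in reg.patients
                if p.documents_of("medical_oncology", "radiation_oncology")]
    n = len(with_doc)
    frac_psy = np.mean([bool(p.documents_of("psychiatry"))
                        for p in with_doc])
    frac_cou = np.mean([bool(p.documents_of("counselling"))
                        for p in with_doc])
    for frac, p0 in ((frac_psy, 0.014), (frac_cou, 0.211)):
        se = np.sqrt(p0 * (1 - p0) / n)
        assert abs(frac - p0) < 3 * se
    # demographic marginals from the same registry
    frac_female = np.mean([p.sex == "female" for p in reg.patients])
    assert abs(frac_female - 0.534) < 3 * np.sqrt(0.534 * 0.466 / len(reg))
    rad = np.mean([p.documents_of("medical_oncology",
                                  "radiation_oncology")[0].specialty
                   == "radiation_oncology" for p in with_doc])
    assert abs(rad - 0.515) < 3 * np.sqrt(0.515 * 0.485 / n)


def test_intercept_solving_matches_marginal_probability():
    """E[sigmoid(b + effects . emissions)] equals the target prevalence
    under the quadrature the solver itself integrates with — checked by
    Monte Carlo over patients."""
    cfg = GeneratorConfig(p_psych=0.05, seed=2, signal_tokens=(
        SignalToken("a", effect_psych=2.0, emit_base=0.3, emit_slope=1.0),
        SignalToken("b", effect_psych=-1.0, emit_base=0.4, emit_slope=0.5),
    ))
    rng = np.random.default_rng(7)
    probs = []
    for _ in range(4000):
        prof = sample_patient(cfg, rng)
        em = sample_emissions(prof, cfg, rng)
        probs.append(label_probability(cfg, "psychiatrist", em))
    assert abs(np.mean(probs) - 0.05) < 0.01


def test_zero_effect_labels_independent_of_emissions():
    cfg = GeneratorConfig(p_psych=0.3, signal_tokens=(
        SignalToken("x", effect_psych=0.0, emit_base=0.5),))
    b = solve_intercept(cfg, "psychiatrist")
    assert label_probability(cfg, "psychiatrist", {"x": True}) == \
        pytest.approx(label_probability(cfg, "psychiatrist", {"x": False}))
    assert 1 / (1 + np.exp(-b)) == pytest.approx(0.3, abs=1e-6)


def test_planted_events_fall_inside_outcome_window():
    cfg = GeneratorConfig(n_patients=3000, seed=13, p_psych=0.2,
                          p_counsel=0.3)
    reg = generate_registry(cfg, render=False)
    for p in reg.patients:
        onc = p.documents_of("medical_oncology", "radiation_oncology")
        if not onc:
            continue
        for ev in p.documents_of("psychiatry", "counselling"):
            assert 1 <= ev.day - onc[0].day <= 365
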