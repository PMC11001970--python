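"""Canonical study conditions for desk-scale experiments.

These configs pin the synthetic-corpus conditions used by the packaged
experiments: a rare-outcome planted-signal corpus for parameter
recovery, a null corpus, an order-sensitive bigram corpus, and a
truncation-sensitivity corpus with signal only beyond the 512-token
boundary.  Model specs are scaled to run on one CPU in minutes: small
embedding/hidden sizes, token budgets of 256 (word models) and 512+
(subword models), undersampling for the neural families (the regime the
transformer comparison prescribes), loss weighting for BoW.
"""

from __future__ import annotations

from .config import GeneratorConfig, SignalToken
from .models import ModelSpec

#: the planted rare-outcome signal: a strong distress marker plus the
#: rule-trigger word at modest strength, both inside the first 240 tokens
PLANTED_SIGNAL_TOKEN = "overwhelmed"  # stems to "overwhelm"


def planted_signal_config(n_patients: int = 20000,
                          seed: int = 0) -> GeneratorConfig:
    """Rare-outcome corpus (prevalence 1.4%) with a known dominant token."""
    return GeneratorConfig(
        n_patients=n_patients, seed=seed,
        p_psych=0.014, p_counsel=0.211,
        signal_tokens=(
            SignalToken(PLANTED_SIGNAL_TOKEN, effect_psych=4.0,
                        effect_counsel=2.0, emit_base=0.15, emit_slope=2.0,
                        region=(20, 240)),
            SignalToken("psychiatrist", effect_psych=1.2, effect_counsel=0.3,
                        emit_base=0.08, emit_slope=1.0, region=(20, 240)),
            SignalToken("counselling", effect_psych=0.3, effect_counsel=1.2,
                        emit_base=0.12, emit_slope=1.0, region=(20, 240)),
        ))


def null_config(n_patients: int = 4000, seed: int = 0) -> GeneratorConfig:
    """Zero-effect corpus: token content independent of the labels."""
    return GeneratorConfig(
        n_patients=n_patients, seed=seed, p_psych=0.10, p_counsel=0.211,
        doc_length_mean=150, doc_length_sd=40, doc_length_min=60,
        signal_tokens=())


def bigram_signal_config(n_patients: int = 3000,
                         seed: int = 0) -> GeneratorConfig:
    """Order-sensitive corpus: the phrase "also noticed" raises the odds,
    its reversal lowers them; unigram counts carry no information."""
    return GeneratorConfig(
        n_patients=n_patients, seed=seed, p_psych=0.5, p_counsel=0.211,
        doc_length_mean=90, doc_length_sd=15, doc_length_min=60,
        p_no_valid_consult=0.0, p_multi_start=0.0,
        signal_tokens=(
            SignalToken("also noticed", effect_psych=3.5,
                        emit_base=0.4, emit_slope=0.0),
            SignalToken("noticed also", effect_psych=-3.5,
                        emit_base=0.4, emit_slope=0.0),
        ))


def truncation_config(n_patients: int = 600, seed: int = 0
                      ) -> GeneratorConfig:
    """Signal planted only beyond token 512: documents of ~660 tokens
    whose only predictive token sits in word positions 525-595 (safely
    past the 512-subword boundary once subword inflation is accounted
    for)."""
    return GeneratorConfig(
        n_patients=n_patients, seed=seed, p_psych=0.5, p_counsel=0.211,
        doc_length_mean=660, doc_length_sd=30, doc_length_min=600,
        p_no_valid_consult=0.0, p_multi_start=0.0,
        signal_tokens=(
            SignalToken(PLANTED_SIGNAL_TOKEN, effect_psych=4.0,
                        emit_base=0.35, emit_slope=1.0, region=(525, 595)),
        ))


def truncation_specs(seed: int = 0) -> dict[int, ModelSpec]:
    """Transformer-slot specs for the truncation-sensitivity experiment:
    the same architecture at token limits 512 and 2048."""
    return {
        limit: toy_spec(
            "transformer", seed=seed, max_tokens=limit,
            n_positions=max(512, limit), embed_dim=8, ff_dim=8,
            min_epochs=6, max_epochs=20)
        for limit in (512, 2048)
    }


def ig_demo_config(n_patients: int = 500, seed: int = 101
                   ) -> GeneratorConfig:
    """Short-document corpus for attribution demonstrations and the
    completeness checks: ~110-token documents, moderate prevalence."""
    return GeneratorConfig(
        n_patients=n_patients, seed=seed, p_psych=0.15, p_counsel=0.25,
        doc_length_mean=110, doc_length_sd=25, doc_length_min=60,
        signal_tokens=(
            SignalToken("overwhelmed", effect_psych=2.5, effect_counsel=1.5,
                        emit_base=0.25, emit_slope=1.5),
            SignalToken("psychiatrist", effect_psych=1.0, emit_base=0.10),
        ))


def toy_spec(family: str, target: str = "psychiatrist", seed: int = 0,
             **overrides) -> ModelSpec:
    """Desk-scale model spec for one family."""
    base = dict(family=family, target=target, seed=seed)
    if family in ("rule", "bow"):
        base.update(imbalance_mode="loss_weighting")
    else:
        base.update(
            imbalance_mode="undersample", embed_dim=12, batch_size=32,
            learning_rate=1e-2, patience=5, min_epochs=10, max_epochs=40,
            n_filters=16, hidden_dim=16, ff_dim=16, dropout=0.3)
        if family == "transformer":
            base.update(max_tokens=512, dev_eval_max=768)
        else:
            base.update(max_tokens=256)
    base.update(overrides)
    return ModelSpec(**base)
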