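"""Configuration objects for the synthetic-corpus generator.

The generator emulates the study population the analysis assumes: ~60k
patients entering cancer care, a 53.4% female share, mean age 64.9 (SD
13.7), documents of ~973 tokens (SD ~354), outcome prevalences of 1.4%
(psychiatry) and 21.1% (counselling), and an even medical/radiation
oncology authorship split.  Signal tokens give the corpus configurable,
known token->outcome effects so downstream models have something real to
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace  # noqa: F401

import yaml


class ConfigError(ValueError):
    """Raised when a generator or experiment configuration is invalid."""


#: Stage mix of the study population (I, II, III, IV, unknown).
DEFAULT_STAGE_PROBS = {
    "I": 6505 / 47625,
    "II": 8817 / 47625,
    "III": 6227 / 47625,
    "IV": 6287 / 47625,
    "unknown": 19789 / 47625,
}


@dataclass(frozen=True)
class SignalToken:
    """A planted token (or phrase) with log-odds effects on the outcomes.

    ``token`` may contain spaces, in which case the whole phrase is
    emitted as consecutive tokens — this is how order-sensitive effects
    are planted.  ``emit_base`` is the emission probability for a patient
    of average latent need; ``emit_slope`` is the log-odds increase in
    emission probability per standard deviation of latent need.
    ``region`` optionally confines the emission to a token-index window of
    the document, which is how truncation-sensitivity corpora are built.
    """

    token: str
    effect_psych: float = 0.0
    effect_counsel: float = 0.0
    emit_base: float = 0.15
    emit_slope: float = 2.0
    region: tuple[int, int] | None = None

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.token.split())


#: Default planted effects: mental-health language raises both outcome
#: odds, referral language is target-specific, retirement is protective.
DEFAULT_SIGNAL_TOKENS = (
    SignalToken("depression", effect_psych=1.6, effect_counsel=1.2),
    SignalToken("anxiety", effect_psych=1.2, effect_counsel=1.0),
    SignalToken("counselling", effect_psych=0.6, effect_counsel=1.6),
    SignalToken("psychiatrist", effect_psych=1.8, effect_counsel=0.4),
    SignalToken("suicidal", effect_psych=2.2, effect_counsel=0.8,
                emit_base=0.04),
    SignalToken("financial", effect_psych=0.2, effect_counsel=0.8),
    SignalToken("retired", effect_psych=-0.4, effect_counsel=-0.6,
                emit_base=0.35, emit_slope=0.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic registry.

    Probabilities default to the study population's observed proportions;
    ``n_multi_start`` / ``n_no_valid_consult`` optionally plant *exact*
    exclusion counts instead of Bernoulli rates.
    """

    n_patients: int = 2000
    p_multi_start: float = 2784 / 59800
    p_no_valid_consult: float = 9391 / 57016
    n_multi_start: int | None = None
    n_no_valid_consult: int | None = None
    p_psych: float = 0.014
    p_counsel: float = 0.211
    doc_length_mean: float = 973.0
    doc_length_sd: float = 354.0
    doc_length_min: int = 50
    age_mean: float = 64.9
    age_sd: float = 13.7
    p_female: float = 0.534
    p_radiation: float = 0.515
    stage_probs: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_STAGE_PROBS.items())
    latent_corr: float = 0.6
    psych_delay_mean_months: float = 5.3
    psych_delay_sd_months: float = 3.4
    counsel_delay_mean_months: float = 2.5
    counsel_delay_sd_months: float = 3.1
    signal_tokens: tuple[SignalToken, ...] = DEFAULT_SIGNAL_TOKENS
    seed: int = 0

    # ---- validation -------------------------------------------------------

    def validate(self) -> "GeneratorConfig":
        import math

        probs = {
            "p_multi_start": self.p_multi_start,
            "p_no_valid_consult": self.p_no_valid_consult,
            "p_psych": self.p_psych, "p_counsel": self.p_counsel,
            "p_female": self.p_female, "p_radiation": self.p_radiation,
            "latent_corr": None,
        }
        for name, p in probs.items():
            if p is None:
                continue
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if not (-1.0 <= self.latent_corr <= 1.0):
            raise ConfigError(
                f"latent_corr must be in [-1, 1], got {self.latent_corr}")
        if self.n_patients < 0:
            raise ConfigError(f"n_patients must be >= 0, got {self.n_patients}")
        if self.doc_length_mean <= 0:
            raise ConfigError(
                f"doc_length_mean must be > 0, got {self.doc_length_mean}")
        if self.doc_length_sd < 0:
            raise ConfigError(
                f"doc_length_sd must be >= 0, got {self.doc_length_sd}")
        stage_total = sum(p for _, p in self.stage_probs)
        if abs(stage_total - 1.0) > 1e-6:
            raise ConfigError(
                f"stage_probs must sum to 1, got {stage_total:.6f}")
        for st in self.signal_tokens:
            for fname in ("effect_psych", "effect_counsel", "emit_slope"):
                v = getattr(st, fname)
                if not math.isfinite(v):
                    raise ConfigError(
                        f"signal_tokens[{st.token!r}].{fname} must be finite")
            if not (0.0 <= st.emit_base <= 1.0):
                raise ConfigError(
                    f"signal_tokens[{st.token!r}].emit_base must be in [0, 1]")
        return self

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_probs"] = dict(self.stage_probs)
        d["signal_tokens"] = [asdict(s) for s in self.signal_tokens]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "stage_probs" in d and isinstance(d["stage_probs"], dict):
            d["stage_probs"] = tuple(d["stage_probs"].items())
        if "signal_tokens" in d:
            sts = []
            for s in d["signal_tokens"]:
                s = dict(s)
                if s.get("region") is not None:
                    s["region"] = tuple(s["region"])
                sts.append(SignalToken(**s))
            d["signal_tokens"] = tuple(sts)
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
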