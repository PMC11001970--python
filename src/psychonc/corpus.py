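"""Synthetic registry and consultation-document generator.

Generates patient registries and sectioned consultation documents with the
statistical structure the downstream analysis assumes, so the whole
pipeline is exercisable without confidential clinical data.

The generative model
--------------------
Each patient carries a latent psychosocial-need score per outcome,
``(z_psych, z_counsel)``, drawn from a standard bivariate normal with
configurable correlation.  Each configured signal token is emitted into
the patient's consultation document with probability
``sigmoid(logit(emit_base) + emit_slope * z)``, where ``z`` is the
relevance-weighted combination of the patient's latent scores.  The
outcome labels are then Bernoulli in the *emissions*::

    P(outcome) = sigmoid(intercept + sum_t effect_t * emitted_t)

with the intercept solved numerically (Gauss-Hermite quadrature over the
latent scores plus emission-pattern enumeration, then bisection) so the
marginal prevalence equals the configured ``p_psych`` / ``p_counsel``.
With all effects zero the labels are independent of the text, giving an
exact null corpus.

Document length is log-normal matched to the configured mean/SD and
floored at ``doc_length_min`` tokens; documents carry the six canonical
consultation sections in order, with filler tokens drawn from a packaged
clinical vocabulary.  For positive patients a psychiatry / counselling
document event is planted at a truncated-normal day offset within the
365-day outcome window.  Everything is deterministic given the config and
its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .config import ConfigError, GeneratorConfig, SignalToken
from .datatypes import ConsultDocument, PatientRecord, Registry
from .vocabulary import (FILLER_VOCABULARY, SECTION_HEADERS, SECTION_WEIGHTS,
                         filler_weights)

__all__ = [
    "PatientProfile", "sample_patient", "sample_emissions",
    "render_document", "generate_registry", "solve_intercept",
]

DAYS_PER_MONTH = 30.44
_HEADER_TOKENS = [h.split() for h in SECTION_HEADERS]
_N_HEADER_TOKENS = sum(len(h) for h in _HEADER_TOKENS)


@dataclass
class PatientProfile:
    """One sampled patient before documents are rendered."""

    patient_id: str
    age: float
    sex: str
    stage: str
    latent_need: dict[str, float]  # keys: psychiatrist, counsellor
    excluded_multi_start: bool = False
    excluded_no_consult: bool = False


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


# ---------------------------------------------------------------------------
# patients


def sample_patient(config: GeneratorConfig, rng: np.random.Generator,
                   patient_id: str = "P000000") -> PatientProfile:
    """Draw one patient: age (truncated normal), sex, stage, latent need."""
    config.validate()
    age = float(rng.normal(config.age_mean, config.age_sd))
    while age < 18.0:
        age = float(rng.normal(config.age_mean, config.age_sd))
    sex = "female" if rng.random() < config.p_female else "male"
    stages, probs = zip(*config.stage_probs)
    stage = str(rng.choice(stages, p=np.asarray(probs) / sum(probs)))
    rho = config.latent_corr
    u, v = rng.standard_normal(2)
    z_p = u
    z_c = rho * u + np.sqrt(max(0.0, 1 - rho * rho)) * v
    return PatientProfile(
        patient_id=patient_id, age=age, sex=sex, stage=stage,
        latent_need={"psychiatrist": float(z_p), "counsellor": float(z_c)})


def _relevance_z(st: SignalToken, latent: dict[str, float]) -> float:
    wp, wc = abs(st.effect_psych), abs(st.effect_counsel)
    if wp + wc == 0.0:
        return 0.5 * (latent["psychiatrist"] + latent["counsellor"])
    return (wp * latent["psychiatrist"] + wc * latent["counsellor"]) / (wp + wc)


def sample_emissions(profile: PatientProfile, config: GeneratorConfig,
                     rng: np.random.Generator) -> dict[str, bool]:
    """Draw which signal tokens this patient's document will contain."""
    out = {}
    for st in config.signal_tokens:
        z = _relevance_z(st, profile.latent_need)
        p = float(_sigmoid(_logit(st.emit_base) + st.emit_slope * z))
        out[st.token] = bool(rng.random() < p)
    return out


# ---------------------------------------------------------------------------
# prevalence-matching intercepts

_GH_NODES = 21


def _emission_pattern_probs(signal_tokens: tuple[SignalToken, ...],
                            latent_corr: float) -> np.ndarray:
    """Marginal probability of each 2^T emission pattern.

    Integrates over the bivariate latent need with Gauss-Hermite
    quadrature; emissions are conditionally independent given the latents.
    """
    T = len(signal_tokens)
    if T == 0:
        return np.ones(1)
    if T > 14:
        raise ConfigError(
            "at most 14 signal tokens supported for exact prevalence "
            f"calibration, got {T}")
    nodes, weights = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    w2 = np.outer(weights, weights).ravel()
    w2 = w2 / w2.sum()
    U, V = np.meshgrid(nodes, nodes, indexing="ij")
    zp = U.ravel()
    zc = latent_corr * U.ravel() + np.sqrt(max(0.0, 1 - latent_corr ** 2)) * V.ravel()
    # per-token emission probability at each quadrature node
    p_tok = np.empty((T, zp.size))
    for t, st in enumerate(signal_tokens):
        wp, wc = abs(st.effect_psych), abs(st.effect_counsel)
        z = 0.5 * (zp + zc) if wp + wc == 0 else (wp * zp + wc * zc) / (wp + wc)
        p_tok[t] = _sigmoid(_logit(st.emit_base) + st.emit_slope * z)
    patterns = np.array(list(itertools.product((0, 1), repeat=T)), dtype=float)
    # P(pattern | node) = prod_t p^e (1-p)^(1-e)
    probs = np.ones((patterns.shape[0], zp.size))
    for t in range(T):
        probs *= np.where(patterns[:, t:t + 1] > 0, p_tok[t], 1 - p_tok[t])
    return probs @ w2


@lru_cache(maxsize=64)
def _solve_intercepts_cached(signal_tokens: tuple[SignalToken, ...],
                             latent_corr: float, p_psych: float,
                             p_counsel: float) -> dict[str, float]:
    pattern_probs = _emission_pattern_probs(signal_tokens, latent_corr)
    T = len(signal_tokens)
    patterns = np.array(list(itertools.product((0, 1), repeat=T)), dtype=float)
    out = {}
    for target, p_target in (("psychiatrist", p_psych),
                             ("counsellor", p_counsel)):
        effects = np.array([
            st.effect_psych if target == "psychiatrist" else st.effect_counsel
            for st in signal_tokens])
        contrib = patterns @ effects if T else np.zeros(1)

        def prevalence(b):
            return float(pattern_probs @ _sigmoid(b + contrib))

        lo, hi = -40.0, 40.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if prevalence(mid) < p_target:
                lo = mid
            else:
                hi = mid
        out[target] = 0.5 * (lo + hi)
    return out


def solve_intercept(config: GeneratorConfig, target: str) -> float:
    """Label-model intercept giving the configured marginal prevalence."""
    if target not in ("psychiatrist", "counsellor"):
        raise ConfigError(f"unknown target: {target!r}")
    p = {"psychiatrist": config.p_psych, "counsellor": config.p_counsel}
    return _solve_intercepts_cached(
        tuple(config.signal_tokens), config.latent_corr,
        config.p_psych, config.p_counsel)[target]


def label_probability(config: GeneratorConfig, target: str,
                      emissions: dict[str, bool]) -> float:
    b = solve_intercept(config, target)
    for st in config.signal_tokens:
        if emissions.get(st.token, False):
            b += (st.effect_psych if target == "psychiatrist"
                  else st.effect_counsel)
    return float(_sigmoid(b))


# ---------------------------------------------------------------------------
# documents

_CUM_WEIGHTS = np.cumsum(filler_weights())
_VOCAB_ARR = np.array(FILLER_VOCABULARY, dtype=object)


def _draw_length(config: GeneratorConfig, rng: np.random.Generator) -> int:
    m, s = config.doc_length_mean, config.doc_length_sd
    if s == 0:
        n = m
    else:
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        n = rng.lognormal(mu, np.sqrt(sigma2))
    return int(max(config.doc_length_min, round(n)))


def render_document(profile: PatientProfile, config: GeneratorConfig,
                    rng: np.random.Generator, *,
                    emissions: dict[str, bool] | None = None,
                    doc_id: str = "D000000", specialty: str | None = None,
                    day: int = 0) -> ConsultDocument:
    """Render one sectioned consultation document for a patient.

    When ``emissions`` is omitted they are sampled here; pass the result
    of :func:`sample_emissions` to keep text and labels consistent.
    """
    config.validate()
    if emissions is None:
        emissions = sample_emissions(profile, config, rng)
    if specialty is None:
        specialty = ("radiation_oncology" if rng.random() < config.p_radiation
                     else "medical_oncology")
    tokens, _ = _build_tokens(profile, config, rng, emissions)
    return ConsultDocument(doc_id=doc_id, patient_id=profile.patient_id,
                           specialty=specialty, day=day,
                           text=_assemble_text(tokens, rng))


def _build_tokens(profile, config, rng, emissions):
    """Token array (headers + filler + planted signals) and section starts."""
    n_total = _draw_length(config, rng)
    n_filler = max(0, n_total - _N_HEADER_TOKENS)
    u = rng.random(n_filler)
    filler = _VOCAB_ARR[np.searchsorted(_CUM_WEIGHTS, u)]

    # lay out sections: header tokens then that section's share of filler
    weights = np.asarray(SECTION_WEIGHTS)
    counts = np.floor(weights / weights.sum() * n_filler).astype(int)
    counts[-1] += n_filler - counts.sum()
    tokens: list[str] = []
    header_pos: set[int] = set()
    pos = 0
    fi = 0
    for head, cnt in zip(_HEADER_TOKENS, counts):
        for h in head:
            tokens.append(h)
            header_pos.add(pos)
            pos += 1
        tokens.extend(filler[fi:fi + cnt])
        fi += cnt
        pos += cnt

    # plant emitted signal phrases, overwriting filler slots
    realized = dict(emissions)
    n = len(tokens)
    for st in config.signal_tokens:
        if not realized.get(st.token, False):
            continue
        phrase = st.tokens
        L = len(phrase)
        lo, hi = (0, n - L) if st.region is None else (
            st.region[0], min(st.region[1], n - L))
        candidates = [
            s for s in range(lo, hi + 1)
            if s >= 0 and not any((s + j) in header_pos for j in range(L))
        ] if hi >= lo else []
        if not candidates:
            realized[st.token] = False  # document too short for the region
            continue
        start = candidates[int(rng.integers(0, len(candidates)))]
        for j, ptok in enumerate(phrase):
            tokens[start + j] = ptok
    emissions.clear()
    emissions.update(realized)
    return tokens, header_pos


def _assemble_text(tokens: list[str], rng: np.random.Generator) -> str:
    """Join tokens into capitalized, period-terminated sentences.

    Header tokens (already uppercase, colon-terminated) start their own
    line.  Every whitespace-delimited chunk keeps at least one
    alphanumeric character, so tokenized counts equal the token budget.
    """
    parts: list[str] = []
    i, n = 0, len(tokens)
    while i < n:
        tok = tokens[i]
        if tok.isupper() or tok.endswith(":"):
            # consume a full header
            parts.append("\n" if parts else "")
            while i < n and (tokens[i].isupper() or tokens[i].endswith(":")):
                parts.append(tokens[i])
                parts.append(" ")
                i += 1
            parts.append("\n")
            continue
        slen = int(rng.integers(6, 15))
        sent = tokens[i:min(i + slen, n)]
        # stop the sentence early if a header follows
        for j, t in enumerate(sent):
            if t.isupper():
                sent = sent[:j]
                break
        if not sent:
            continue
        i += len(sent)
        sent = [str(t) for t in sent]
        sent[0] = sent[0][:1].upper() + sent[0][1:]
        parts.append(" ".join(sent) + ". ")
    return "".join(parts).strip()


# ---------------------------------------------------------------------------
# registry


def _truncated_delay(rng, mean_days: float, sd_days: float) -> int:
    """Day offset in (0, 365], resampled from a normal until it fits."""
    for _ in range(1000):
        d = int(round(rng.normal(mean_days, sd_days)))
        if 1 <= d <= 365:
            return d
    return int(np.clip(round(mean_days), 1, 365))


def generate_registry(config: GeneratorConfig, *,
                      render: bool = True) -> Registry:
    """Generate a full synthetic registry, deterministic given the seed.

    ``render=False`` replaces document prose with a minimal text carrying
    only the planted signal tokens — orders of magnitude faster when only
    registry-level statistics are needed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return Registry(patients=[])

    # exclusion flags: multi-start first, then no-valid-consult among rest
    multi = np.zeros(n, dtype=bool)
    if config.n_multi_start is not None:
        k = min(config.n_multi_start, n)
        multi[rng.choice(n, size=k, replace=False)] = True
    else:
        multi = rng.random(n) < config.p_multi_start
    rest = np.flatnonzero(~multi)
    noconsult = np.zeros(n, dtype=bool)
    if config.n_no_valid_consult is not None:
        k = min(config.n_no_valid_consult, rest.size)
        noconsult[rng.choice(rest, size=k, replace=False)] = True
    else:
        noconsult[rest] = rng.random(rest.size) < config.p_no_valid_consult

    psych_delay = (config.psych_delay_mean_months * DAYS_PER_MONTH,
                   config.psych_delay_sd_months * DAYS_PER_MONTH)
    counsel_delay = (config.counsel_delay_mean_months * DAYS_PER_MONTH,
                     config.counsel_delay_sd_months * DAYS_PER_MONTH)

    patients: list[PatientRecord] = []
    for i in range(n):
        pid = f"P{i:06d}"
        profile = sample_patient(config, rng, patient_id=pid)
        profile.excluded_multi_start = bool(multi[i])
        profile.excluded_no_consult = bool(noconsult[i])
        diagnosis_day = int(rng.integers(0, 2100))
        emissions = sample_emissions(profile, config, rng)

        docs: list[ConsultDocument] = []
        onc_day = None
        if noconsult[i]:
            if rng.random() < 0.5:  # half have no consult at all
                onc_day = diagnosis_day + 181 + int(rng.integers(0, 120))
        else:
            offset = int(np.clip(round(abs(rng.normal(30.0, 35.0))), 0, 180))
            onc_day = diagnosis_day + offset
        if onc_day is not None:
            if render:
                doc = render_document(
                    profile, config, rng, emissions=emissions,
                    doc_id=f"D{i:06d}", day=onc_day)
            else:
                spec_name = ("radiation_oncology"
                             if rng.random() < config.p_radiation
                             else "medical_oncology")
                emitted = [t for st in config.signal_tokens
                           for t in st.tokens if emissions.get(st.token)]
                doc = ConsultDocument(
                    doc_id=f"D{i:06d}", patient_id=pid, specialty=spec_name,
                    day=onc_day,
                    text=" ".join(emitted) if emitted else "consultation")
            docs.append(doc)

            # outcome labels and planted clinician-contact events
            if rng.random() < label_probability(config, "psychiatrist",
                                                emissions):
                day = onc_day + _truncated_delay(rng, *psych_delay)
                docs.append(ConsultDocument(
                    doc_id=f"D{i:06d}_psy", patient_id=pid,
                    specialty="psychiatry", day=day,
                    text="Seen by psychiatry for assessment."))
            if rng.random() < label_probability(config, "counsellor",
                                                emissions):
                day = onc_day + _truncated_delay(rng, *counsel_delay)
                docs.append(ConsultDocument(
                    doc_id=f"D{i:06d}_cou", patient_id=pid,
                    specialty="counselling", day=day,
                    text="Seen by counselling for support."))

        patients.append(PatientRecord(
            patient_id=pid, diagnosis_day=diagnosis_day, age=profile.age,
            sex=profile.sex, stage=profile.stage,
            multi_start=bool(multi[i]), documents=docs))
    return Registry(patients=patients)
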