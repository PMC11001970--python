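"""Model interpretation: coefficient ranking, integrated gradients,
attribution-filtered sentence extraction.

Three complementary views of what a trained model uses:

* :func:`rank_coefficients` — feature importance of the bag-of-words
  logistic regression by absolute coefficient weight.
* :func:`integrated_gradients` — per-token attributions for the neural
  models: the score gradient is integrated along the straight path in
  embedding space from a baseline (an all-padding sequence by default) to
  the document, giving attributions that sum to the score difference
  (completeness).
* :func:`salient_sentences` — sentences whose mean token attribution
  exceeds a threshold (0.01 by default), drawn from the first 1500
  tokens of each document; feeding these to the topic stage summarizes a
  model's behaviour over a whole corpus rather than one document.
"""

from __future__ import annotations

import html as _html
import re
from dataclasses import dataclass, field

import numpy as np

from .cohort import TokenSeq, tokenize
from .models.bow import BowModel
from .models.trainer import SequenceModel

__all__ = ["AttributionMap", "SalientSentenceSet", "rank_coefficients",
           "integrated_gradients", "salient_sentences",
           "attribution_html"]


@dataclass
class AttributionMap:
    """Per-token attributions for one document."""

    doc_id: str
    tokens: list[str]
    attributions: np.ndarray
    baseline: str
    score: float
    baseline_score: float

    @property
    def completeness_residual(self) -> float:
        return float(abs(self.attributions.sum()
                         - (self.score - self.baseline_score)))


@dataclass
class SalientSentenceSet:
    """Sentences retained by the mean-attribution filter."""

    sentences: list[tuple[str, str, float]]  # (doc_id, text, mean attr)
    threshold: float = 0.01
    trim: int = 1500

    def texts(self) -> list[str]:
        return [s for _, s, _ in self.sentences]


def rank_coefficients(model: BowModel, k: int = 10
                      ) -> list[tuple[str, float, str]]:
    """Top-k tokens of a BoW model by |coefficient|, with direction.

    Ties break lexicographically; ``k`` beyond the vocabulary returns the
    full ranking.  Returns (token, coefficient, direction) triples where
    direction is "positive", "negative" or "zero".
    """
    coefs = model.coefficients()
    ranked = sorted(coefs.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    out = []
    for token, c in ranked[:max(0, k)]:
        direction = "positive" if c > 0 else ("negative" if c < 0 else "zero")
        out.append((token, float(c), direction))
    return out


def integrated_gradients(model: SequenceModel, seq: TokenSeq,
                         steps: int = 50, output: str = "prob",
                         doc_id: str = "") -> AttributionMap:
    """Integrated-gradients attributions for one tokenized document.

    The baseline is the all-padding sequence of equal length (a zero
    embedding row).  The path integral is approximated with the
    trapezoid rule over ``steps`` interpolation points, evaluated as one
    batch.  ``output='logit'`` attributes the raw logit instead of the
    sigmoid score.
    """
    if isinstance(model, BowModel):
        raise TypeError(
            "integrated gradients needs a differentiable sequence model; "
            "use rank_coefficients for bag-of-words models")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    X, mask, tokens = model.embed(seq)
    baseline = np.zeros_like(X)  # padding embedding row is frozen at zero
    alphas = np.linspace(0.0, 1.0, steps + 1)
    batch = baseline[None] + alphas[:, None, None] * (X - baseline)[None]
    masks = np.repeat(mask[None, :], steps + 1, axis=0)
    scores, grads = model.forward_from_embeddings(batch, masks, output=output)
    # trapezoid weights over the path
    w = np.full(steps + 1, 1.0 / steps)
    w[0] = w[-1] = 0.5 / steps
    avg_grad = np.tensordot(w, grads, axes=1)
    attr = ((X - baseline) * avg_grad).sum(axis=1)
    return AttributionMap(
        doc_id=doc_id, tokens=tokens, attributions=attr,
        baseline="all-padding sequence",
        score=float(scores[-1]), baseline_score=float(scores[0]))


# ---------------------------------------------------------------------------
# sentence extraction

_ABBREVIATIONS = ("dr.", "mr.", "mrs.", "ms.", "mg.", "mcg.", "vs.", "st.")
_BOUNDARY = re.compile(r"([.!?])(\s+)(?=[A-Z0-9])")


def split_sentences(text: str) -> list[str]:
    """Split on ., ! or ? followed by whitespace and an uppercase start,
    protecting common clinical abbreviations.  Header lines (ALL CAPS
    ending with a colon) become their own segments."""
    segments: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        prev_word = text[start:m.end(1)].rsplit(None, 1)
        if prev_word and prev_word[-1].lower() in _ABBREVIATIONS:
            continue
        segments.append(text[start:m.end(1)].strip())
        start = m.end()
    tail = text[start:].strip()
    if tail:
        segments.append(tail)
    out: list[str] = []
    for seg in segments:
        for line in seg.splitlines():
            line = line.strip()
            if line:
                out.append(line)
    return out


def salient_sentences(model: SequenceModel, docs, threshold: float = 0.01,
                      trim: int = 1500, steps: int = 50,
                      dialect: str = "neural") -> SalientSentenceSet:
    """Extract sentences with mean token attribution above ``threshold``.

    ``docs`` is an iterable of (doc_id, text).  Each document is trimmed
    to its first ``trim`` tokens before attribution; only sentences whose
    token span lies entirely within the trimmed prefix are eligible, and
    only positive mean attributions are retained (the analysis targets
    positive predictors).  Output order is by (doc_id, position), so it
    is invariant to the order documents are supplied in.
    """
    kept: list[tuple[str, int, str, float]] = []
    for doc_id, text in docs:
        sents = split_sentences(text)
        sent_tokens = [tokenize(s, dialect).tokens for s in sents]
        full = TokenSeq(dialect=dialect,
                        tokens=tuple(t for st in sent_tokens for t in st))
        if len(full.tokens) == 0:
            continue
        seq = TokenSeq(dialect=dialect, tokens=full.tokens[:trim])
        amap = integrated_gradients(model, seq, steps=steps, doc_id=doc_id)
        attr = amap.attributions
        offset = 0
        for pos, (sent, toks) in enumerate(zip(sents, sent_tokens)):
            span = len(toks)
            if span == 0:
                continue
            if offset + span > len(attr):
                break  # sentence extends beyond the trimmed prefix
            mean_attr = float(attr[offset:offset + span].mean())
            if mean_attr > threshold:
                kept.append((doc_id, pos, sent, mean_attr))
            offset += span
    kept.sort(key=lambda t: (t[0], t[1]))
    return SalientSentenceSet(
        sentences=[(d, s, a) for d, _, s, a in kept],
        threshold=threshold, trim=trim)


def attribution_html(amap: AttributionMap) -> str:
    """Heat-text view of one document's attributions (red positive,
    blue negative), for writing to an output directory."""
    peak = float(np.abs(amap.attributions).max()) or 1.0
    spans = []
    for tok, a in zip(amap.tokens, amap.attributions):
        alpha = min(1.0, abs(a) / peak)
        color = (255, 80, 80) if a >= 0 else (80, 80, 255)
        spans.append(
            f'<span title="{a:+.4f}" style="background-color:'
            f'rgba({color[0]},{color[1]},{color[2]},{alpha:.2f})">'
            f"{_html.escape(tok)}</span>")
    body = " ".join(spans)
    return (f"<html><body><p>doc {_html.escape(amap.doc_id)} — score "
            f"{amap.score:.3f} (baseline {amap.baseline_score:.3f})</p>"
            f"<p>{body}</p></body></html>")
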