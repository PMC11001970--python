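"""WordPiece-style subword vocabulary for the transformer dialect.

No pretrained subword vocabulary ships with this package, so the
transformer dialect segments words with a vocabulary trained on the
corpus at hand: frequent whole words stay intact and rarer words are
split greedily into the longest matching pieces, continuation pieces
carrying the conventional ``##`` prefix.  Unmatched characters fall back
to single-character pieces, so encoding is total.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

_ALPHABET = "abcdefghijklmnopqrstuvwxyz0123456789"


@dataclass
class SubwordVocab:
    """Greedy longest-match subword segmenter."""

    pieces: frozenset[str] = field(
        default_factory=lambda: frozenset(_ALPHABET))

    def __post_init__(self) -> None:
        # always able to fall back to single characters
        base = set(self.pieces)
        base.update(_ALPHABET)
        base.update("##" + c for c in _ALPHABET)
        self.pieces = frozenset(base)
        self._cache: dict[str, tuple[str, ...]] = {}

    @classmethod
    def build(cls, words, vocab_size: int = 8000,
              min_freq: int = 2) -> "SubwordVocab":
        """Train from an iterable of (already lowercased) word tokens.

        Whole words with frequency >= min_freq enter the vocabulary by
        descending frequency, then frequent word prefixes and suffix
        continuations provide mid-size pieces for everything else.
        """
        freqs = Counter(words)
        pieces: set[str] = set()
        for w, c in freqs.most_common():
            if len(pieces) >= vocab_size:
                break
            if c >= min_freq:
                pieces.add(w)
        # mid-size pieces from word morphology: prefixes of length 3..6 and
        # their continuations, weighted by how many distinct words share them
        prefix_counts: Counter[str] = Counter()
        suffix_counts: Counter[str] = Counter()
        for w, c in freqs.items():
            for k in range(3, min(7, len(w))):
                prefix_counts[w[:k]] += 1
                suffix_counts["##" + w[k:]] += 1
        budget = max(0, vocab_size + 2000 - len(pieces))
        for piece, _ in (prefix_counts + suffix_counts).most_common(budget):
            pieces.add(piece)
        return cls(pieces=frozenset(pieces))

    def encode_word(self, word: str) -> tuple[str, ...]:
        cached = self._cache.get(word)
        if cached is not None:
            return cached
        out: list[str] = []
        i, n = 0, len(word)
        while i < n:
            prefix = "##" if i else ""
            piece = None
            for j in range(n, i, -1):
                cand = prefix + word[i:j]
                if cand in self.pieces:
                    piece = cand
                    i = j
                    break
            if piece is None:  # unknown character
                piece = prefix + word[i]
                i += 1
            out.append(piece)
        res = tuple(out)
        if len(self._cache) < 1_000_000:
            self._cache[word] = res
        return res


@lru_cache(maxsize=1)
def _default_vocab() -> SubwordVocab:
    from .vocabulary import FILLER_VOCABULARY

    return SubwordVocab.build(FILLER_VOCABULARY, min_freq=1)


class _DefaultVocabProxy:
    """Lazily built default vocabulary over the packaged word list."""

    def encode_word(self, word: str) -> tuple[str, ...]:
        return _default_vocab().encode_word(word)


DEFAULT_SUBWORD_VOCAB = _DefaultVocabProxy()
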