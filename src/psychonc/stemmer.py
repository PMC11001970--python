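"""Suffix-stripping stemmer for the bag-of-words token dialect.

Reduces words to stems by removing endings ("anxieties" -> "anxieti",
"depression" -> "depress", "counselling" -> "counsel", "anxious" ->
"anxious").  This is the English Snowball ("Porter2") algorithm,
implemented here self-contained so the stem surface forms used throughout
the package — including in the rule-based comparator and the coefficient
tables — are stable and reproducible.

Non-alphabetic tokens (numerals such as "1") are returned unchanged.
"""

from __future__ import annotations

from functools import lru_cache

__all__ = ["porter_stem", "stem_tokens"]

_VOWELS = frozenset("aeiouy")
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_LI_ENDING = frozenset("cdeghkmnrt")

# Irregular forms stemmed (or frozen) directly.
_EXCEPTIONS1 = {
    "skis": "ski", "skies": "sky", "dying": "die", "lying": "lie",
    "tying": "tie", "idly": "idl", "gently": "gentl", "ugly": "ugli",
    "early": "earli", "only": "onli", "singly": "singl",
    "sky": "sky", "news": "news", "howe": "howe", "atlas": "atlas",
    "cosmos": "cosmos", "bias": "bias", "andes": "andes",
}
# Words left untouched after step 1a.
_EXCEPTIONS2 = frozenset(
    ["inning", "outing", "canning", "herring", "earring",
     "proceed", "exceed", "succeed"]
)

_STEP2 = (
    ("ization", "ize"), ("ational", "ate"), ("fulness", "ful"),
    ("ousness", "ous"), ("iveness", "ive"), ("tional", "tion"),
    ("biliti", "ble"), ("lessli", "less"), ("entli", "ent"),
    ("ation", "ate"), ("alism", "al"), ("aliti", "al"), ("ousli", "ous"),
    ("iviti", "ive"), ("fulli", "ful"), ("enci", "ence"), ("anci", "ance"),
    ("abli", "able"), ("izer", "ize"), ("ator", "ate"), ("alli", "al"),
    ("bli", "ble"),
)

_STEP3 = (
    ("ational", "ate"), ("tional", "tion"), ("alize", "al"),
    ("icate", "ic"), ("iciti", "ic"), ("ical", "ic"),
    ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "ement", "ance", "ence", "able", "ible", "ment",
    "ant", "ent", "ism", "ate", "iti", "ous", "ive", "ize",
    "ion", "al", "er", "ic",
)


def _is_vowel(w: str, i: int) -> bool:
    return w[i] in _VOWELS and w[i] != "Y"


def _mark_consonant_y(w: str) -> str:
    # y at the start or after a vowel acts as a consonant; mark it Y.
    chars = list(w)
    if chars[0] == "y":
        chars[0] = "Y"
    for i in range(1, len(chars)):
        if chars[i] == "y" and chars[i - 1] in "aeiouy" and chars[i - 1] != "Y":
            chars[i] = "Y"
    return "".join(chars)


def _regions(w: str) -> tuple[int, int]:
    """Start indices of R1 and R2."""
    n = len(w)
    r1 = n
    for pre in ("gener", "commun", "arsen"):
        if w.startswith(pre):
            r1 = len(pre)
            break
    else:
        for i in range(1, n):
            if not _is_vowel(w, i) and _is_vowel(w, i - 1):
                r1 = i + 1
                break
    r2 = n
    for i in range(r1 + 1, n):
        if not _is_vowel(w, i) and _is_vowel(w, i - 1):
            r2 = i + 1
            break
    return r1, r2


def _ends_short_syllable(w: str) -> bool:
    n = len(w)
    if n == 2:
        return _is_vowel(w, 0) and not _is_vowel(w, 1)
    if n >= 3:
        return (
            not _is_vowel(w, n - 3)
            and _is_vowel(w, n - 2)
            and not _is_vowel(w, n - 1)
            and w[n - 1] not in "wxY"
        )
    return False


def _is_short_word(w: str, r1: int) -> bool:
    return r1 >= len(w) and _ends_short_syllable(w)


def _contains_vowel(w: str) -> bool:
    return any(_is_vowel(w, i) for i in range(len(w)))


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith(("ied", "ies")):
        return w[:-2] if len(w) > 4 else w[:-1]
    if w.endswith(("us", "ss")):
        return w
    if w.endswith("s") and _contains_vowel(w[:-2]):
        return w[:-1]
    return w


def _step1b(w: str, r1: int) -> str:
    for suffix in ("eedly", "eed"):
        if w.endswith(suffix):
            if len(w) - len(suffix) >= r1:
                return w[: -len(suffix)] + "ee"
            return w
    for suffix in ("ingly", "edly", "ing", "ed"):
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if not _contains_vowel(stem):
                return w
            if stem.endswith(("at", "bl", "iz")):
                return stem + "e"
            if stem.endswith(_DOUBLES):
                return stem[:-1]
            if _is_short_word(stem, r1):
                return stem + "e"
            return stem
    return w


def _step1c(w: str) -> str:
    if len(w) > 2 and w[-1] in "yY" and w[-2] not in "aeiouy":
        return w[:-1] + "i"
    return w


def _step2(w: str, r1: int) -> str:
    for suffix, repl in _STEP2:
        if w.endswith(suffix):
            if len(w) - len(suffix) >= r1:
                return w[: -len(suffix)] + repl
            return w
    if w.endswith("ogi"):
        if len(w) - 3 >= r1 and w[-4:-3] == "l":
            return w[:-1]
        return w
    if w.endswith("li"):
        if len(w) - 2 >= r1 and w[-3:-2] in _LI_ENDING:
            return w[:-2]
        return w
    return w


def _step3(w: str, r1: int, r2: int) -> str:
    for suffix, repl in _STEP3:
        if w.endswith(suffix):
            if len(w) - len(suffix) >= r1:
                return w[: -len(suffix)] + repl
            return w
    if w.endswith("ative"):
        if len(w) - 5 >= r2:
            return w[:-5]
        return w
    return w


def _step4(w: str, r2: int) -> str:
    for suffix in _STEP4:
        if w.endswith(suffix):
            if len(w) - len(suffix) >= r2:
                if suffix == "ion" and w[-4:-3] not in ("s", "t"):
                    return w
                return w[: -len(suffix)]
            return w
    return w


def _step5(w: str, r1: int, r2: int) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        if len(stem) >= r2 or (
            len(stem) >= r1 and not _ends_short_syllable(stem)
        ):
            return stem
        return w
    if w.endswith("l") and len(w) - 1 >= r2 and w[-2:-1] == "l":
        return w[:-1]
    return w


@lru_cache(maxsize=262144)
def porter_stem(token: str) -> str:
    """Stem a single lowercase token.

    Tokens shorter than three characters or containing any non-letter are
    returned unchanged, so numerals survive as their own tokens.
    """
    if len(token) <= 2 or not token.isalpha():
        return token
    if token in _EXCEPTIONS1:
        return _EXCEPTIONS1[token]
    w = _mark_consonant_y(token)
    r1, r2 = _regions(w)
    w = _step1a(w)
    if w in _EXCEPTIONS2:
        return w
    w = _step1b(w, r1)
    w = _step1c(w)
    w = _step2(w, r1)
    w = _step3(w, r1, r2)
    w = _step4(w, r2)
    w = _step5(w, r1, r2)
    return w.replace("Y", "y")


def stem_tokens(tokens: list[str]) -> list[str]:
    return [porter_stem(t) for t in tokens]
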