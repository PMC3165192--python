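"""Porter stemming.

Effect-word matching and rule-node matching are stem-based so that surface
inflection ("induce", "induces", "inducer", "inducing") collapses onto one
rulebook key. This is the classic Porter (1980) suffix-stripping algorithm:
five rule steps applied in sequence, each conditioned on the *measure* m of
the remaining stem, where a word is viewed as [C](VC)^m[V] over consonant (C)
and vowel (V) runs.
"""

from __future__ import annotations

__all__ = ["stem"]

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        # y is a vowel when preceded by a consonant
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in the [C](VC)^m[V] decomposition."""
    m = 0
    i = 0
    n = len(stem)
    while i < n and _is_consonant(stem, i):
        i += 1
    while i < n:
        while i < n and not _is_consonant(stem, i):
            i += 1
        if i >= n:
            break
        m += 1
        while i < n and _is_consonant(stem, i):
            i += 1
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    """*o condition: stem ends cvc where the final c is not w, x or y."""
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace(word: str, suffix: str, repl: str, min_measure: int) -> str | None:
    """Replace suffix if present and the remaining stem has measure > min_measure."""
    if not word.endswith(suffix):
        return None
    stem_part = word[: len(word) - len(suffix)]
    if _measure(stem_part) > min_measure:
        return stem_part + repl
    return word  # suffix matched but condition failed: no further rule in the step fires


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            return w[:-1]
        return w
    hit = None
    if w.endswith("ed") and _has_vowel(w[:-2]):
        hit = w[:-2]
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        hit = w[:-3]
    if hit is None:
        return w
    # cleanup after ed/ing removal
    if hit.endswith(("at", "bl", "iz")):
        return hit + "e"
    if _ends_double_consonant(hit) and hit[-1] not in "lsz":
        return hit[:-1]
    if _measure(hit) == 1 and _ends_cvc(hit):
        return hit + "e"
    return hit


def _step1c(w: str) -> str:
    if w.endswith("y") and _has_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _step2(w: str) -> str:
    for suffix, repl in _STEP2:
        if w.endswith(suffix):
            out = _replace(w, suffix, repl, 0)
            return out if out is not None else w
    return w


def _step3(w: str) -> str:
    for suffix, repl in _STEP3:
        if w.endswith(suffix):
            out = _replace(w, suffix, repl, 0)
            return out if out is not None else w
    return w


def _step4(w: str) -> str:
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem_part = w[: len(w) - len(suffix)]
            if suffix == "ion" and not stem_part.endswith(("s", "t")):
                return w
            if _measure(stem_part) > 1:
                return stem_part
            return w
    return w


def _step5a(w: str) -> str:
    if w.endswith("e"):
        m = _measure(w[:-1])
        if m > 1 or (m == 1 and not _ends_cvc(w[:-1])):
            return w[:-1]
    return w


def _step5b(w: str) -> str:
    if _ends_double_consonant(w) and w[-1] == "l" and _measure(w[:-1]) > 1:
        return w[:-1]
    return w


def stem(word: str) -> str:
    """Porter stem of a single token, case-folded.

    Deterministic, and idempotent on common vocabulary (the stemmer maps
    stems to themselves); words of length <= 2 are returned unchanged per
    the original algorithm.
    """
    w = word.casefold()
    if len(w) <= 2:
        return w
    for step in (_step1a, _step1b, _step1c, _step2, _step3, _step4, _step5a, _step5b):
        w = step(w)
    return w
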