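"""Classic Porter (1980) stemming algorithm.

Suffix-stripping in five steps driven by the *measure* m of a stem, the
number of vowel-consonant sequences in its consonant/vowel skeleton.  This is
the original algorithm, not the later "Porter2"/Snowball revision: step 2
keeps the 1980 suffix table (e.g. ``abli -> able``) and no ``logi`` rule.

Words of length <= 2 are returned unchanged.
"""

from __future__ import annotations

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        # y is a consonant at position 0 or after a vowel
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in the C?(VC)^m V? skeleton of ``stem``."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        cons = _is_cons(stem, i)
        if cons and prev_vowel:
            m += 1
        prev_vowel = not cons
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    """consonant-vowel-consonant ending, final consonant not w, x or y."""
    if len(word) < 3:
        return False
    n = len(word)
    return (
        _is_cons(word, n - 3)
        and not _is_cons(word, n - 2)
        and _is_cons(word, n - 1)
        and word[-1] not in "wxy"
    )


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
    flag = False
    if w.endswith("ed") and _has_vowel(w[:-2]):
        w, flag = w[:-2], True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w, flag = w[:-3], True
    if flag:
        if w.endswith(("at", "bl", "iz")):
            return w + "e"
        if _ends_double_cons(w) and w[-1] not in "lsz":
            return w[:-1]
        if _measure(w) == 1 and _ends_cvc(w):
            return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _has_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


_STEP2 = [
    ("ational", "ate"),
    ("tional", "tion"),
    ("enci", "ence"),
    ("anci", "ance"),
    ("izer", "ize"),
    ("abli", "able"),
    ("alli", "al"),
    ("entli", "ent"),
    ("eli", "e"),
    ("ousli", "ous"),
    ("ization", "ize"),
    ("ation", "ate"),
    ("ator", "ate"),
    ("alism", "al"),
    ("iveness", "ive"),
    ("fulness", "ful"),
    ("ousness", "ous"),
    ("aliti", "al"),
    ("iviti", "ive"),
    ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"),
    ("ative", ""),
    ("alize", "al"),
    ("iciti", "ic"),
    ("ical", "ic"),
    ("ful", ""),
    ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _replace_longest(w: str, table: list[tuple[str, str]], min_m: int) -> str:
    # longest matching suffix wins; its m-condition is final (no fallback)
    best = None
    for suffix, repl in table:
        if w.endswith(suffix) and (best is None or len(suffix) > len(best[0])):
            best = (suffix, repl)
    if best is not None:
        suffix, repl = best
        stem = w[: len(w) - len(suffix)]
        if _measure(stem) > min_m - 1:
            return stem + repl
    return w


def _step4(w: str) -> str:
    best = None
    for suffix in _STEP4:
        if w.endswith(suffix) and (best is None or len(suffix) > len(best)):
            best = suffix
    if best is not None:
        stem = w[: len(w) - len(best)]
        if _measure(stem) > 1:
            if best == "ion" and (not stem or stem[-1] not in "st"):
                return w
            return stem
    return w


def _step5a(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            return stem
    return w


def _step5b(w: str) -> str:
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        return w[:-1]
    return w


def porter_stem(token: str) -> str:
    """Stem one lowercase token with the classic Porter algorithm."""
    if len(token) <= 2:
        return token
    w = _step1a(token)
    w = _step1b(w)
    w = _step1c(w)
    w = _replace_longest(w, _STEP2, min_m=1)
    w = _replace_longest(w, _STEP3, min_m=1)
    w = _step4(w)
    w = _step5a(w)
    w = _step5b(w)
    return w
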