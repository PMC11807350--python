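"""Light text-processing primitives: tokenization, sentence segmentation,
and a Porter-family suffix-stripping stemmer.

Sentence segmentation follows an unsupervised punctuation-based rule set:
a sentence ends at ``. ! ?`` (optionally followed by closing quotes or
brackets) when followed by whitespace, unless the period belongs to a
decimal number, a single-letter initial, or a known abbreviation.  The
segmenter is deliberately simple and deterministic; it is pluggable
wherever it is consumed downstream.
"""

from __future__ import annotations

import re

__all__ = ["tokenize", "segment_sentences", "porter_stem", "ABBREVIATIONS"]

_TOKEN_RE = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)?|\d+(?:\.\d+)?")

#: Abbreviations whose trailing period never ends a sentence.
ABBREVIATIONS = frozenset(
    {
        "e.g", "i.e", "et al", "etc", "vs", "cf", "fig", "figs", "eq", "ref",
        "refs", "dr", "prof", "mr", "mrs", "ms", "no", "vol", "pp", "ca",
        "approx", "resp", "inc", "ltd", "jr", "sr", "st",
    }
)


def tokenize(text: str) -> list[str]:
    """Lowercased word/number tokens."""
    return [t.lower() for t in _TOKEN_RE.findall(text)]


_BOUNDARY_RE = re.compile(r"[.!?]+[\"'\)\]]*\s")


def _is_abbreviation(text: str, punct_idx: int) -> bool:
    """Does the period at ``punct_idx`` terminate an abbreviation or initial?"""
    if text[punct_idx] != ".":
        return False
    head = text[:punct_idx]
    m = re.search(r"([A-Za-z][A-Za-z.]*)$", head)
    if not m:
        return False
    word = m.group(1).lower().rstrip(".")
    if len(word) == 1:  # single-letter initial, "p." in "p. 3" or "J. Smith"
        return True
    if word in ABBREVIATIONS:
        return True
    # multi-word abbreviations like "et al."
    if head.lower().endswith("et al"):
        return True
    return False


def segment_sentences(body: str) -> list[tuple[int, int]]:
    """Split ``body`` into sentence offsets (0-based, end-exclusive).

    Returns non-overlapping, ordered spans whose slices are the sentences,
    trimmed of surrounding whitespace, jointly covering all non-whitespace
    text.  An empty or all-whitespace body yields ``[]``.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(body):
        punct_idx = m.start()
        end = m.end() - 1  # exclude the trailing whitespace char
        nxt = body[m.end():].lstrip()
        if _is_abbreviation(body, punct_idx):
            continue
        # require the next sentence to start like one (capital, digit, quote
        # or bracket); otherwise treat the period as internal
        if nxt and not (nxt[0].isupper() or nxt[0].isdigit() or nxt[0] in "\"'(["):
            continue
        spans.append((start, end))
        start = m.end()
    if start < len(body):
        spans.append((start, len(body)))
    # trim whitespace while preserving offsets
    out: list[tuple[int, int]] = []
    for s, e in spans:
        while s < e and body[s].isspace():
            s += 1
        while e > s and body[e - 1].isspace():
            e -= 1
        if s < e:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Porter stemmer (classic 1980 algorithm, steps 1a-5b)
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """The number of VC sequences (the 'm' of the algorithm)."""
    forms = "".join("c" if _is_cons(stem, i) else "v" for i in range(len(stem)))
    forms = re.sub(r"c+", "C", forms)
    forms = re.sub(r"v+", "V", forms)
    return forms.count("VC")


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return len(word) >= 2 and word[-1] == word[-2] and _is_cons(word, len(word) - 1)


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (_is_cons(word, len(word) - 3) and not _is_cons(word, len(word) - 2)
            and _is_cons(word, len(word) - 1)):
        return False
    return word[-1] not in "wxy"


def _replace(word: str, suffix: str, repl: str, m_min: int) -> str | None:
    if word.endswith(suffix):
        stem = word[: len(word) - len(suffix)]
        if _measure(stem) > m_min:
            return stem + repl
    return None


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]
_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]
_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement", "ment",
    "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(word: str) -> str:
    """Stem a lowercase word with the classic suffix-stripping algorithm.

    ``funding`` -> ``fund``, ``financed``/``finance`` -> ``financ``.
    """
    w = word.lower()
    if len(w) <= 2:
        return w

    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    # step 1b
    flag = False
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed") and _has_vowel(w[:-2]):
        w, flag = w[:-2], True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w, flag = w[:-3], True
    if flag:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _ends_double_cons(w) and not w.endswith(("l", "s", "z")):
            w = w[:-1]
        elif _measure(w) == 1 and _ends_cvc(w):
            w += "e"

    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # step 2
    for suf, repl in _STEP2:
        if w.endswith(suf):
            res = _replace(w, suf, repl, 0)
            if res is not None:
                w = res
            break

    # step 3
    for suf, repl in _STEP3:
        if w.endswith(suf):
            res = _replace(w, suf, repl, 0)
            if res is not None:
                w = res
            break

    # step 4
    for suf in _STEP4:
        if w.endswith(suf):
            stem = w[: len(w) - len(suf)]
            if suf == "ion" and not stem.endswith(("s", "t")):
                break
            if _measure(stem) > 1:
                w = stem
            break

    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem
    # step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]
    return w
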