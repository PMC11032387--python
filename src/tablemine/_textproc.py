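"""Deterministic English text preprocessing for abstracts.

Tokenization (lowercased alphabetic words), stop-word removal (sklearn's
built-in English list by default) and a small rule-based suffix lemmatizer.
The lemmatizer is intentionally simple and fully deterministic: pair
filtering only depends on whether two processed abstracts share any token
at all, not on linguistically perfect lemmas.
"""

from __future__ import annotations

import re

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

_WORD_RE = re.compile(r"[a-z]+")

_IRREGULAR = {
    "men": "man", "women": "woman", "mice": "mouse", "children": "child",
    "feet": "foot", "teeth": "tooth", "analyses": "analysis",
    "hypotheses": "hypothesis", "data": "datum", "criteria": "criterion",
}

_VOWELS = set("aeiou")


def _strip_double_consonant(word: str) -> str:
    # un-double trailing consonants (running -> run) but keep -ll/-ss/-zz
    if (len(word) >= 2 and word[-1] == word[-2]
            and word[-1] not in _VOWELS and word[-1] not in "lsz"):
        return word[:-1]
    return word


def lemmatize(word: str) -> str:
    """Reduce common English inflections by suffix rules."""
    if word in _IRREGULAR:
        return _IRREGULAR[word]
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("es") and len(word) > 3 and word[-3] in "sxz":
        return word[:-2]
    if word.endswith("s") and len(word) > 3 and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    if word.endswith("ing") and len(word) > 5:
        return _strip_double_consonant(word[:-3])
    if word.endswith("ed") and len(word) > 4:
        return _strip_double_consonant(word[:-2])
    return word


def preprocess_text(text: str, stopword_list: frozenset[str] | set[str] | None = None) -> list[str]:
    """Lowercase word tokens with stop-words removed and inflections reduced."""
    stopwords = ENGLISH_STOP_WORDS if stopword_list is None else stopword_list
    out = []
    for match in _WORD_RE.finditer(text.lower()):
        word = match.group(0)
        if word in stopwords:
            continue
        lemma = lemmatize(word)
        if lemma and lemma not in stopwords:
            out.append(lemma)
    return out
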