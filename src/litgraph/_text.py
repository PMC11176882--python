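"""Tokenization, normalization and language-screening primitives.

Everything in here is deliberately deterministic: the default pipeline
(NFKC + casefold, stopword removal, conservative plural stripping) is a
pure function of its input, so mention extraction and the fixtures built
on top of it are reproducible byte for byte.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Callable, Iterable

# Small standard English stopword list. Level modifiers ("high",
# "increased") and causative connectors ("induces") are NOT stopwords:
# they are legal utility nodes of the network.
STOPWORDS: frozenset[str] = frozenset(
    """a about above after again against all also an and any are as at be
    because been before being below between both but by can could did do
    does down during each few for from further had has have having he her
    here hers him his how i if in into is it its itself just may might
    more most no nor not now of off on once only or other our out over
    own same she should so some such than that the their them then there
    these they this those through to too under until up very was we were
    what when where which while who whom why will with would you your""".split()
)

# Word tokens: alphanumeric runs, optionally hyphen-joined ("sars-cov-2").
_TOKEN_RE = re.compile(r"[0-9a-z]+(?:-[0-9a-z]+)*")


def normalize_text(text: str) -> str:
    """NFKC-normalize and casefold a string."""
    return unicodedata.normalize("NFKC", text).casefold()


def default_lemmatize(token: str) -> str:
    """Conservative suffix-stripping lemmatizer (plural reduction only).

    Intentionally weak: it never invents stems that could collide across
    concepts ("induces" is left alone, "vaccines" -> "vaccine",
    "studies" -> "study").
    """
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("sses"):
        return token[:-2]
    if token.endswith("s") and len(token) > 3 and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


Lemmatizer = Callable[[str], str]


@dataclass(frozen=True)
class Token:
    """One word token with its raw surface and normalized/lemmatized forms."""

    raw: str
    norm: str
    lemma: str
    is_stop: bool


def tokenize(
    text: str,
    lemmatize: Lemmatizer = default_lemmatize,
    stopwords: frozenset[str] = STOPWORDS,
) -> list[Token]:
    """Split text into :class:`Token` objects.

    Hyphenated compounds are kept whole so ontology surfaces such as
    "sars-cov-2" survive as a single token.
    """
    tokens: list[Token] = []
    norm_text = normalize_text(text)
    for m in _TOKEN_RE.finditer(norm_text):
        norm = m.group(0)
        tokens.append(
            Token(raw=norm, norm=norm, lemma=lemmatize(norm), is_stop=norm in stopwords)
        )
    return tokens


def content_tokens(tokens: Iterable[Token]) -> list[Token]:
    """Drop stopword tokens."""
    return [t for t in tokens if not t.is_stop]


def phrase_key(
    surface: str,
    lemmatize: Lemmatizer = default_lemmatize,
    stopwords: frozenset[str] = STOPWORDS,
) -> tuple[str, ...]:
    """Canonical lookup key for a multi-word surface form.

    Applied identically to lexicon surfaces and to candidate n-grams from
    documents, so dictionary matching is insensitive to case, plural
    inflection and embedded stopwords.
    """
    return tuple(t.lemma for t in content_tokens(tokenize(surface, lemmatize, stopwords)))


def ascii_ratio(text: str) -> float:
    if not text:
        return 1.0
    return sum(1 for c in text if ord(c) < 128) / len(text)


def is_probably_english(text: str, min_ascii: float = 0.85) -> bool:
    """Cheap language screen: ASCII ratio plus a stopword hit.

    Texts long enough to carry function words (>= 6 tokens) must contain
    at least one English stopword; shorter strings pass on the ASCII
    ratio alone. This is a heuristic predicate and is pluggable wherever
    it is used.
    """
    if ascii_ratio(text) < min_ascii:
        return False
    toks = [m.group(0) for m in _TOKEN_RE.finditer(normalize_text(text))]
    if len(toks) >= 6:
        return any(t in STOPWORDS for t in toks)
    return True
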