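"""Corpus ingestion and entity mining.

This module turns a raw publication-metadata table (CORD-19
``metadata.csv`` dialect) into a cleaned, deduplicated corpus, extracts
ontology-term mentions from title + abstract with a deterministic
dictionary matcher, and curates the mentions into the entity table that
seeds the co-occurrence network.

Cleaning rules
--------------
* records without an abstract are dropped;
* records whose title fails an (pluggable) English screen are dropped;
* records dated before ``min_year`` that mention any exclusion term
  (by default the MERS/SARS/coronavirus family) are dropped;
* record-id clusters are reconciled to a single record: the
  peer-reviewed one (journal present) if available, else the row richest
  in metadata.

Entity curation discards mentions whose normalized Levenshtein
similarity to the linked concept surface falls below a threshold
(default 0.7, inclusive); utility terms are always retained.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import edlib
import pandas as pd

from ._text import (
    STOPWORDS,
    Lemmatizer,
    Token,
    content_tokens,
    default_lemmatize,
    is_probably_english,
    normalize_text,
    phrase_key,
    tokenize,
)
from .lexicon import Lexicon, LexiconTerm
from .network import ConceptEntity

logger = logging.getLogger(__name__)

#: Metadata fields counted when picking the "richest" row of a cluster.
RICHNESS_FIELDS = (
    "title",
    "abstract",
    "publish_time",
    "journal",
    "authors",
    "doi",
    "num_cited_by",
)

#: Default pre-``min_year`` exclusion terms (earlier coronavirus literature).
DEFAULT_EXCLUSION_TERMS = (
    "MERS",
    "Middle East Respiratory Syndrome",
    "SARS",
    "Severe Acute Respiratory Syndrome",
    "coronavirus",
)

DEFAULT_MIN_YEAR = 2020

_YEAR_RE = re.compile(r"\b(19|20)\d{2}\b")


@dataclass(frozen=True)
class PublicationRecord:
    """One cleaned corpus document."""

    record_id: str
    title: str
    abstract: str
    publish_time: date | None = None
    date_precision: str = "day"  # "day" | "year"
    journal: str | None = None
    authors: str | None = None
    doi: str | None = None
    num_cited_by: int | None = None

    @property
    def peer_reviewed(self) -> bool:
        return bool(self.journal)

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()


@dataclass(frozen=True)
class MentionRecord:
    """One linked entity mention (a row of the raw-entity table)."""

    record_id: str
    surface_span: str
    matched_term: LexiconTerm
    similarity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError(f"similarity {self.similarity} outside [0, 1]")


@dataclass
class EntityTable:
    """Curated entities plus the per-document entity sets derived with them."""

    entities: dict[str, ConceptEntity] = field(default_factory=dict)
    doc_entities: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entities)


# ---------------------------------------------------------------------------
# cleaning / deduplication


def _nonempty(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    s = str(value).strip()
    return s or None


def _parse_date(raw: str | None, precision_hint: str | None = None):
    """Return (date, precision) or (None, None) when unparseable.

    Full ISO dates keep day precision; anything else falls back to a
    4-digit year stored as January 1 with a ``year`` precision marker.
    """
    if raw is None:
        return None, None
    raw = raw.strip()
    if precision_hint == "year":
        m = _YEAR_RE.search(raw)
        if m:
            return date(int(m.group(0)), 1, 1), "year"
    try:
        return date.fromisoformat(raw[:10]), "day"
    except ValueError:
        pass
    m = _YEAR_RE.search(raw)
    if m:
        return date(int(m.group(0)), 1, 1), "year"
    return None, None


def _richness(row: Mapping) -> int:
    return sum(1 for f in RICHNESS_FIELDS if _nonempty(row.get(f)) is not None)


def clean_and_dedupe(
    raw_rows: pd.DataFrame | Iterable[Mapping],
    min_year: int = DEFAULT_MIN_YEAR,
    exclusion_terms: Sequence[str] = DEFAULT_EXCLUSION_TERMS,
    english_predicate: Callable[[str], bool] = is_probably_english,
    id_column: str = "cord_uid",
) -> list[PublicationRecord]:
    """Clean a raw metadata table and reconcile duplicate clusters.

    Returns the retained :class:`PublicationRecord` objects sorted by
    record id. The operation is idempotent: re-cleaning its own output
    (round-tripped through :func:`records_to_frame`) changes nothing.
    """
    if isinstance(raw_rows, pd.DataFrame):
        rows = raw_rows.to_dict("records")
    else:
        rows = list(raw_rows)

    exclusion_folded = [normalize_text(t) for t in exclusion_terms]
    clusters: dict[str, list[tuple[int, Mapping, PublicationRecord]]] = {}
    n_dropped = {"no_id": 0, "no_abstract": 0, "language": 0, "date": 0, "excluded": 0}

    for order, row in enumerate(rows):
        record_id = _nonempty(row.get(id_column)) or _nonempty(row.get("record_id"))
        if record_id is None:
            n_dropped["no_id"] += 1
            logger.warning("row %d dropped: missing record id", order)
            continue
        abstract = _nonempty(row.get("abstract"))
        if abstract is None:
            n_dropped["no_abstract"] += 1
            continue
        title = _nonempty(row.get("title")) or ""
        if not english_predicate(title or abstract):
            n_dropped["language"] += 1
            continue
        pub_date, precision = _parse_date(
            _nonempty(row.get("publish_time")), _nonempty(row.get("date_precision"))
        )
        if _nonempty(row.get("publish_time")) is not None and pub_date is None:
            n_dropped["date"] += 1
            logger.warning("record %s dropped: unparseable date %r", record_id, row.get("publish_time"))
            continue
        if pub_date is not None and pub_date.year < min_year:
            haystack = normalize_text(f"{title} {abstract}")
            if any(term in haystack for term in exclusion_folded):
                n_dropped["excluded"] += 1
                continue
        cited = _nonempty(row.get("num_cited_by"))
        record = PublicationRecord(
            record_id=record_id,
            title=title,
            abstract=abstract,
            publish_time=pub_date,
            date_precision=precision or "day",
            journal=_nonempty(row.get("journal")),
            authors=_nonempty(row.get("authors")),
            doi=_nonempty(row.get("doi")),
            num_cited_by=int(float(cited)) if cited is not None else None,
        )
        clusters.setdefault(record_id, []).append((order, row, record))

    kept: list[PublicationRecord] = []
    n_merged = 0
    for record_id in sorted(clusters):
        candidates = clusters[record_id]
        if len(candidates) > 1:
            n_merged += 1
            peer = [c for c in candidates if c[2].peer_reviewed]
            pool = peer or candidates
            # richest in metadata; ties resolved by original row order
            pool = sorted(pool, key=lambda c: (-_richness(c[1]), c[0]))
            candidates = [pool[0]]
        kept.append(candidates[0][2])

    logger.info(
        "clean_and_dedupe: %d rows in, %d records kept, %d clusters merged, dropped %s",
        len(rows), len(kept), n_merged, n_dropped,
    )
    return kept


def records_to_frame(records: Iterable[PublicationRecord]) -> pd.DataFrame:
    """Cleaned corpus as a DataFrame in the input schema plus ``date_precision``."""
    rows = []
    for r in records:
        rows.append(
            {
                "cord_uid": r.record_id,
                "title": r.title,
                "abstract": r.abstract,
                "publish_time": r.publish_time.isoformat() if r.publish_time else "",
                "date_precision": r.date_precision if r.publish_time else "",
                "journal": r.journal or "",
                "authors": r.authors or "",
                "doi": r.doi or "",
                "num_cited_by": "" if r.num_cited_by is None else str(r.num_cited_by),
            }
        )
    return pd.DataFrame(rows)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False).replace({"": None})


def write_corpus_csv(records: Iterable[PublicationRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_corpus_csv(path: str | Path) -> list[PublicationRecord]:
    """Load a previously cleaned corpus without re-applying any filter."""
    out = []
    for row in read_metadata_csv(path).to_dict("records"):
        pub_date, precision = _parse_date(
            _nonempty(row.get("publish_time")), _nonempty(row.get("date_precision"))
        )
        cited = _nonempty(row.get("num_cited_by"))
        out.append(
            PublicationRecord(
                record_id=row["cord_uid"],
                title=_nonempty(row.get("title")) or "",
                abstract=_nonempty(row.get("abstract")) or "",
                publish_time=pub_date,
                date_precision=precision or "day",
                journal=_nonempty(row.get("journal")),
                authors=_nonempty(row.get("authors")),
                doi=_nonempty(row.get("doi")),
                num_cited_by=int(float(cited)) if cited is not None else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# similarity


def normalized_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity: ``1 - d(a, b) / max(|a|, |b|)``.

    Symmetric, equals 1 iff the strings are identical, 0 when every
    position differs. Raises :class:`ValueError` on an empty argument.
    """
    if not a or not b:
        raise ValueError("normalized_similarity requires non-empty strings")
    distance = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - distance / max(len(a), len(b))


# ---------------------------------------------------------------------------
# mention extraction


class DictionaryMatcher:
    """Deterministic longest-match-first dictionary annotator.

    Surfaces are indexed by their normalized content-token key (case
    folded, stopwords removed, plural-stripped); document text is scanned
    left to right over its content tokens, preferring the longest n-gram
    with a lexicon hit, without overlaps. Any callable with the same
    ``(record) -> list[MentionRecord]`` signature can replace it (e.g. a
    statistical NER backend).
    """

    def __init__(
        self,
        lexicon: Lexicon,
        lemmatize: Lemmatizer = default_lemmatize,
        stopwords: frozenset[str] = STOPWORDS,
        similarity_on: str = "raw",
    ) -> None:
        if similarity_on not in ("raw", "lemma"):
            raise ValueError("similarity_on must be 'raw' or 'lemma'")
        self.lemmatize = lemmatize
        self.stopwords = stopwords
        self.similarity_on = similarity_on
        self._table: dict[tuple[str, ...], list[LexiconTerm]] = {}
        self.max_ngram = 1
        for term in lexicon.terms:
            key = phrase_key(term.surface_form, lemmatize, stopwords)
            if not key:
                logger.warning("lexicon surface %r normalizes to nothing; unmatchable", term.surface_form)
                continue
            bucket = self._table.setdefault(key, [])
            if term not in bucket:
                bucket.append(term)
            self.max_ngram = max(self.max_ngram, len(key))
        for bucket in self._table.values():
            bucket.sort(key=lambda t: t.concept_id)

    def __call__(self, record: PublicationRecord) -> list[MentionRecord]:
        tokens = content_tokens(tokenize(record.text, self.lemmatize, self.stopwords))
        return self._scan(record.record_id, tokens)

    def _scan(self, record_id: str, tokens: list[Token]) -> list[MentionRecord]:
        mentions: list[MentionRecord] = []
        lemmas = [t.lemma for t in tokens]
        i = 0
        while i < len(tokens):
            matched_n = 0
            for n in range(min(self.max_ngram, len(tokens) - i), 0, -1):
                terms = self._table.get(tuple(lemmas[i : i + n]))
                if terms:
                    span_tokens = tokens[i : i + n]
                    raw_span = " ".join(t.raw for t in span_tokens)
                    cmp_span = (
                        raw_span
                        if self.similarity_on == "raw"
                        else " ".join(t.lemma for t in span_tokens)
                    )
                    for term in terms:
                        mentions.append(
                            MentionRecord(
                                record_id=record_id,
                                surface_span=raw_span,
                                matched_term=term,
                                similarity=normalized_similarity(cmp_span, term.surface_form),
                            )
                        )
                    matched_n = n
                    break
            i += matched_n or 1
        return mentions


def extract_mentions(
    record: PublicationRecord,
    lexicon: Lexicon,
    matcher: Callable[[PublicationRecord], list[MentionRecord]] | None = None,
) -> list[MentionRecord]:
    """Extract linked mentions from one record's title + abstract.

    ``matcher`` may be any pluggable annotator; the default is a
    :class:`DictionaryMatcher` built from ``lexicon``.
    """
    if matcher is None:
        matcher = DictionaryMatcher(lexicon)
    return matcher(record)


def extract_corpus_mentions(
    records: Iterable[PublicationRecord],
    lexicon: Lexicon,
    matcher: Callable[[PublicationRecord], list[MentionRecord]] | None = None,
) -> list[MentionRecord]:
    """Run mention extraction over a whole corpus with one shared matcher."""
    if matcher is None:
        matcher = DictionaryMatcher(lexicon)
    mentions: list[MentionRecord] = []
    for record in records:
        mentions.extend(matcher(record))
    logger.info("extracted %d mentions", len(mentions))
    return mentions


# ---------------------------------------------------------------------------
# entity curation


def curate_entities(
    mentions: Iterable[MentionRecord],
    threshold: float = 0.7,
) -> EntityTable:
    """Aggregate mentions into curated entities.

    Mentions below the similarity ``threshold`` (inclusive cut: 0.70
    survives, 0.69 does not) are discarded unless they are utility
    terms. Entity frequency is the number of *distinct* documents
    mentioning the concept.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    docs_per_concept: dict[str, set[str]] = {}
    term_per_concept: dict[str, LexiconTerm] = {}
    doc_entities: dict[str, set[str]] = {}
    n_discarded = 0
    for m in mentions:
        term = m.matched_term
        if not term.is_utility and m.similarity < threshold:
            n_discarded += 1
            continue
        name = term.concept_name
        docs_per_concept.setdefault(name, set()).add(m.record_id)
        term_per_concept.setdefault(name, term)
        doc_entities.setdefault(m.record_id, set()).add(name)

    entities = {}
    for name, docs in docs_per_concept.items():
        term = term_per_concept[name]
        entities[name] = ConceptEntity(
            name=name,
            umls_id=term.umls_id,
            cido_id=term.cido_id,
            macrocategory=term.macrocategory,
            semantic_type=term.semantic_type,
            frequency=len(docs),
        )
    logger.info(
        "curated %d entities from %d documents (%d low-similarity mentions discarded)",
        len(entities), len(doc_entities), n_discarded,
    )
    return EntityTable(entities=entities, doc_entities=doc_entities)


# ---------------------------------------------------------------------------
# mentions TSV round-trip

MENTIONS_COLUMNS = ("record_id", "span", "concept", "similarity")


def write_mentions_tsv(mentions: Iterable[MentionRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MENTIONS_COLUMNS)
        for m in mentions:
            writer.writerow(
                [m.record_id, m.surface_span, m.matched_term.concept_id, f"{m.similarity:.6f}"]
            )


def read_mentions_tsv(path: str | Path, lexicon: Lexicon) -> list[MentionRecord]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            term = lexicon.concept_index.get(row["concept"])
            if term is None:
                logger.warning("mention references unknown concept id %r; skipped", row["concept"])
                continue
            out.append(
                MentionRecord(
                    record_id=row["record_id"],
                    surface_span=row["span"],
                    matched_term=term,
                    similarity=float(row["similarity"]),
                )
            )
    return out
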