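"""Ontology lexicon: the legal node universe of the co-occurrence network.

The lexicon maps term surface forms to biomedical concepts drawn from two
terminologies — UMLS (generic medical vocabulary, organised in
macrocategories and semantic types) and CIDO (a community COVID-19
ontology with a flat concept structure) — plus a user-extensible list of
*utility* terms: level modifiers ("high", "increased") and causative
connectors ("induces") that are admitted as network nodes even though no
ontology defines them.

File format: TSV with header ``surface\tname\tumls_id\tcido_id\t
macrocategory\ttype``; utility terms come from a plain text file, one
term per line.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from ._text import normalize_text

logger = logging.getLogger(__name__)

#: UMLS macrocategories recognised for network nodes.
UMLS_MACROCATEGORIES: tuple[str, ...] = (
    "ACTIVITIES_AND_BEHAVIORS",
    "ANATOMY",
    "CHEMICALS_AND_DRUGS",
    "CONCEPTS_AND_IDEAS",
    "DEVICES",
    "DISORDERS",
    "ENTITY",
    "GENES_AND_MOLECULAR_SEQUENCES",
    "GEOGRAPHIC_AREAS",
    "LIVING_BEINGS",
    "OBJECTS",
    "OCCUPATIONS",
    "ORGANIZATIONS",
    "PHENOMENA",
    "PHYSIOLOGY",
    "PROCEDURES",
)

UTILITY_MACROCATEGORY = "UTILITY"

#: Default utility-term list; user-extensible through the utility file.
DEFAULT_UTILITY_TERMS: tuple[str, ...] = ("high", "increased", "induces")

#: Common alternate spellings normalised on load.
_MACROCATEGORY_ALIASES = {
    "GENES_AND_MOLECOLAR_SEQUENCES": "GENES_AND_MOLECULAR_SEQUENCES",
}

REQUIRED_COLUMNS = ("surface", "name", "umls_id", "cido_id", "macrocategory", "type")


class LexiconError(ValueError):
    """Base class for lexicon loading problems."""


class LexiconFormatError(LexiconError):
    """The lexicon file is malformed (e.g. a required column is missing)."""


class EmptyLexiconError(LexiconError):
    """The lexicon file contains no terms."""


@dataclass(frozen=True)
class LexiconTerm:
    """One surface form linked to a concept (or a utility term).

    ``surface_form`` is case-folded; non-utility terms carry at least one
    of ``umls_id`` / ``cido_id``; utility terms carry neither and live in
    the ``UTILITY`` macrocategory.
    """

    surface_form: str
    concept_name: str
    umls_id: str | None = None
    cido_id: str | None = None
    macrocategory: str = UTILITY_MACROCATEGORY
    semantic_type: str | None = None
    is_utility: bool = False

    def __post_init__(self) -> None:
        if not self.surface_form:
            raise LexiconFormatError("surface_form must be non-empty")
        folded = normalize_text(self.surface_form)
        if folded != self.surface_form:
            object.__setattr__(self, "surface_form", folded)
        has_id = self.umls_id is not None or self.cido_id is not None
        if self.is_utility:
            if has_id or self.macrocategory != UTILITY_MACROCATEGORY:
                raise LexiconFormatError(
                    f"utility term {self.surface_form!r} must have no ontology id "
                    f"and macrocategory {UTILITY_MACROCATEGORY}"
                )
        else:
            if not has_id:
                raise LexiconFormatError(
                    f"term {self.surface_form!r} has neither a UMLS nor a CIDO id"
                )
            if self.macrocategory == UTILITY_MACROCATEGORY:
                raise LexiconFormatError(
                    f"non-utility term {self.surface_form!r} cannot be {UTILITY_MACROCATEGORY}"
                )

    @property
    def concept_id(self) -> str:
        """Stable identifier: UMLS id, else CIDO id, else a utility key."""
        if self.umls_id:
            return self.umls_id
        if self.cido_id:
            return self.cido_id
        return f"UTILITY:{self.surface_form}"


@dataclass
class Lexicon:
    """Indexed collection of :class:`LexiconTerm`.

    ``index`` maps case-folded surface forms to terms; ``concept_index``
    maps every ontology id (UMLS and CIDO alike) to one term.
    """

    terms: list[LexiconTerm] = field(default_factory=list)
    index: dict[str, list[LexiconTerm]] = field(default_factory=dict)
    concept_index: dict[str, LexiconTerm] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def add(self, term: LexiconTerm) -> None:
        self.terms.append(term)
        self.index.setdefault(term.surface_form, []).append(term)
        for cid in (term.umls_id, term.cido_id):
            if cid is not None:
                existing = self.concept_index.get(cid)
                if existing is not None and existing.concept_name != term.concept_name:
                    raise LexiconFormatError(
                        f"concept id {cid} maps to two names: "
                        f"{existing.concept_name!r} and {term.concept_name!r}"
                    )
                self.concept_index.setdefault(cid, term)
        if term.is_utility:
            self.concept_index.setdefault(term.concept_id, term)

    def utility_terms(self) -> list[LexiconTerm]:
        return [t for t in self.terms if t.is_utility]


def _clean(value: str | None) -> str | None:
    if value is None:
        return None
    value = value.strip()
    return value or None


def load_lexicon(path: str | Path, utility_path: str | Path | None = None) -> Lexicon:
    """Load a lexicon TSV plus an optional utility-term file.

    Rows sharing the same (surface form, concept name) are merged into a
    single term carrying the union of their ontology ids, so a concept
    defined by both UMLS and CIDO keeps both identifiers. Raises
    :class:`LexiconFormatError` on a missing column and
    :class:`EmptyLexiconError` when no term survives loading.
    """
    path = Path(path)
    merged: dict[tuple[str, str], LexiconTerm] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise LexiconFormatError(f"lexicon file {path} lacks required column {col!r}")
        for row in reader:
            surface = normalize_text((row["surface"] or "").strip())
            if not surface:
                continue
            macro = (row["macrocategory"] or "").strip()
            macro = _MACROCATEGORY_ALIASES.get(macro, macro)
            if macro not in UMLS_MACROCATEGORIES and macro != UTILITY_MACROCATEGORY:
                logger.warning("unknown macrocategory %r for surface %r", macro, surface)
            term = LexiconTerm(
                surface_form=surface,
                concept_name=(row["name"] or "").strip() or surface,
                umls_id=_clean(row["umls_id"]),
                cido_id=_clean(row["cido_id"]),
                macrocategory=macro,
                semantic_type=_clean(row["type"]),
            )
            key = (term.surface_form, term.concept_name)
            if key in merged:
                prev = merged[key]
                merged[key] = replace(
                    prev,
                    umls_id=prev.umls_id or term.umls_id,
                    cido_id=prev.cido_id or term.cido_id,
                    semantic_type=prev.semantic_type or term.semantic_type,
                )
            else:
                merged[key] = term

    lexicon = Lexicon()
    for key in sorted(merged):
        lexicon.add(merged[key])

    if utility_path is not None:
        for term in load_utility_terms(utility_path):
            lexicon.add(term)

    if not lexicon.terms:
        raise EmptyLexiconError(f"lexicon file {path} contains no terms")
    return lexicon


def load_utility_terms(path: str | Path) -> list[LexiconTerm]:
    """Read one utility term per line (blank lines and ``#`` comments skipped)."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(make_utility_term(line))
    return out


def make_utility_term(surface: str) -> LexiconTerm:
    surface = normalize_text(surface.strip())
    return LexiconTerm(
        surface_form=surface,
        concept_name=surface,
        macrocategory=UTILITY_MACROCATEGORY,
        is_utility=True,
    )


def default_utility_lexicon_terms() -> list[LexiconTerm]:
    return [make_utility_term(s) for s in DEFAULT_UTILITY_TERMS]


def lookup(lexicon: Lexicon, surface: str) -> list[LexiconTerm]:
    """Exact case-folded surface lookup; results ordered by concept id."""
    matches = lexicon.index.get(normalize_text(surface), [])
    return sorted(matches, key=lambda t: t.concept_id)


def build_lexicon(terms: Iterable[LexiconTerm]) -> Lexicon:
    """Assemble a lexicon from in-memory terms (fixtures, tests)."""
    lexicon = Lexicon()
    for term in terms:
        lexicon.add(term)
    if not lexicon.terms:
        raise EmptyLexiconError("no terms supplied")
    return lexicon


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write the ontology terms back to TSV (utility terms excluded)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for term in lexicon.terms:
            if term.is_utility:
                continue
            writer.writerow(
                [
                    term.surface_form,
                    term.concept_name,
                    term.umls_id or "",
                    term.cido_id or "",
                    term.macrocategory,
                    term.semantic_type or "",
                ]
            )
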