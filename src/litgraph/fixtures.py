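"""Synthetic corpora and the worked search example.

Nothing here touches the network or external data: fixture corpora are
small synthetic stand-ins for a real publication-metadata table, with
abstracts assembled as bags of lexicon surface forms glued together by
filler stopwords, so the deterministic dictionary matcher recovers the
planted entity sets exactly and every downstream count is known by
construction.

Two generators are provided:

* :func:`generate_corpus` — randomized corpora with controlled marginal
  and joint mention probabilities, fully determined by a seed;
* :func:`worked_example_fixture` — a hand-built corpus that reproduces the
  worked search example: a 6-concept, 5-relationship query over a
  network in which one query edge expands to three alternative 3-hop
  paths, one to a single 2-hop path, and three exist directly; the two
  focal publications score 4.5 and 11/3. All concept ids and the
  coordinate-labelled intermediate nodes ("(1,0)", "(2,1)", ...) are
  synthetic. Two different intermediates would both be labelled "(1,0)"
  by their local expansion coordinates, so the second is named
  "(1,0)'".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .lexicon import Lexicon, LexiconTerm, build_lexicon
from .network import edge_key
from .pipeline import PipelineResult, run_pipeline
from .query import GraphQuery

_FILLER_PREFIX = "In this synthetic cohort study we observe that"
_FILLER_SUFFIX = "are jointly reported under controlled conditions."
_EMPTY_ABSTRACT = (
    "In this synthetic cohort study we report a general observation "
    "under controlled conditions with no specific findings."
)


def _abstract_for(surfaces: list[str]) -> str:
    if not surfaces:
        return _EMPTY_ABSTRACT
    return f"{_FILLER_PREFIX} {' and '.join(surfaces)} {_FILLER_SUFFIX}"


def _row(record_id: str, i: int, abstract: str, publish_time: str) -> dict:
    return {
        "cord_uid": record_id,
        "title": f"Synthetic study number {i}",
        "abstract": abstract,
        "publish_time": publish_time,
        "journal": "Journal of Synthetic Studies",
        "authors": "Doe, J.; Roe, R.",
        "doi": f"10.0000/synthetic.{record_id}",
        "num_cited_by": str(i % 7),
    }


# ---------------------------------------------------------------------------
# randomized corpora


@dataclass
class CorpusSpec:
    """Parameters of a randomized synthetic corpus.

    ``pair_affinities`` maps concept-name pairs to the probability that
    a document mentions both jointly; ``baseline_rate`` is the
    independent per-entity mention probability; the last ``n_empty``
    documents carry no entity at all (they still count toward corpus
    size). The seed fully determines the output.
    """

    n_docs: int
    vocabulary: list[LexiconTerm]
    pair_affinities: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline_rate: float = 0.1
    n_empty: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.vocabulary:
            raise ValueError("vocabulary must be non-empty")
        if not 0.0 <= self.baseline_rate <= 1.0:
            raise ValueError("baseline_rate outside [0, 1]")
        for pair, p in self.pair_affinities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"affinity {p} for {pair} outside [0, 1]")
        if not 0 <= self.n_empty <= self.n_docs:
            raise ValueError("n_empty outside [0, n_docs]")


def generate_corpus(spec: CorpusSpec) -> tuple[pd.DataFrame, Lexicon]:
    """Generate a raw metadata table plus its lexicon from ``spec``.

    Deterministic: the same spec (same seed) produces byte-identical
    CSV output. Pair affinities are applied in sorted pair order, then
    baseline mentions in vocabulary order.
    """
    rng = np.random.default_rng(spec.seed)
    by_name = {t.concept_name: t for t in spec.vocabulary}
    for a, b in spec.pair_affinities:
        if a not in by_name or b not in by_name:
            raise ValueError(f"affinity pair ({a!r}, {b!r}) not in vocabulary")
    order = [t.concept_name for t in spec.vocabulary]
    rows = []
    start = date(2020, 1, 1)
    for i in range(spec.n_docs):
        planted: set[str] = set()
        if i < spec.n_docs - spec.n_empty:
            for (a, b) in sorted(spec.pair_affinities):
                if rng.random() < spec.pair_affinities[(a, b)]:
                    planted.update((a, b))
            for name in order:
                if rng.random() < spec.baseline_rate:
                    planted.add(name)
        else:
            rng.random(len(spec.pair_affinities) + len(order))  # keep stream aligned
        surfaces = [by_name[n].surface_form for n in order if n in planted]
        day = start + timedelta(days=int(rng.integers(0, 1096)))
        rows.append(_row(f"syn{i:05d}", i, _abstract_for(surfaces), day.isoformat()))
    frame = pd.DataFrame(rows)
    return frame, build_lexicon(spec.vocabulary)


def perfect_pair_corpus(
    n_docs: int = 10, n_joint: int = 3, seed: int = 0
) -> tuple[pd.DataFrame, Lexicon]:
    """A corpus where two entities co-occur in ``n_joint`` documents and
    never appear apart; the remaining documents mention nothing.

    With marginals equal to the joint count and ``n_joint < n_docs``,
    the resulting edge has NPMI exactly 1.
    """
    if not 1 <= n_joint <= n_docs:
        raise ValueError("need 1 <= n_joint <= n_docs")
    vocabulary = [
        LexiconTerm(
            surface_form="alpha factor",
            concept_name="Alpha Factor",
            umls_id="C9100001",
            macrocategory="CHEMICALS_AND_DRUGS",
            semantic_type="Biologically Active Substance",
        ),
        LexiconTerm(
            surface_form="beta factor",
            concept_name="Beta Factor",
            umls_id="C9100002",
            macrocategory="CHEMICALS_AND_DRUGS",
            semantic_type="Biologically Active Substance",
        ),
    ]
    spec = CorpusSpec(
        n_docs=n_docs,
        vocabulary=vocabulary,
        pair_affinities={("Alpha Factor", "Beta Factor"): 1.0},
        baseline_rate=0.0,
        n_empty=n_docs - n_joint,
        seed=seed,
    )
    return generate_corpus(spec)


# ---------------------------------------------------------------------------
# the worked search example

#: (concept name, surface form, synthetic UMLS-style id, macrocategory, type)
_WEX_CONCEPTS: tuple[tuple[str, str, str, str, str], ...] = (
    ("SARS-CoV-2", "sars-cov-2", "C9000001", "LIVING_BEINGS", "Virus"),
    ("ACE2", "ace2", "C9000002", "GENES_AND_MOLECULAR_SEQUENCES", "Gene or Genome"),
    ("AngII", "angiotensin ii", "C9000003", "CHEMICALS_AND_DRUGS", "Hormone"),
    ("Vascular Permeability", "vascular permeability", "C9000004", "PHYSIOLOGY", "Organ or Tissue Function"),
    ("Hypertension", "hypertension", "C9000005", "DISORDERS", "Disease or Syndrome"),
    ("Inflammation", "inflammation", "C9000006", "DISORDERS", "Pathologic Function"),
    ("(1,0)", "c10", "C9000007", "PHENOMENA", "Biologic Function"),
    ("(1,1)", "c11", "C9000008", "PHENOMENA", "Biologic Function"),
    ("(2,0)", "c20", "C9000009", "PHENOMENA", "Biologic Function"),
    ("(2,1)", "c21", "C9000010", "PHENOMENA", "Biologic Function"),
    ("(3,0)", "c30", "C9000011", "PHENOMENA", "Biologic Function"),
    ("(3,1)", "c31", "C9000012", "PHENOMENA", "Biologic Function"),
    ("(1,0)'", "c10b", "C9000013", "PHENOMENA", "Biologic Function"),
)

#: The 14 network edges the fixture is designed to keep after pruning.
_WEX_EDGES: tuple[tuple[str, str], ...] = tuple(
    edge_key(a, b)
    for a, b in (
        # query edges present directly in the network
        ("ACE2", "AngII"),
        ("AngII", "Hypertension"),
        ("Hypertension", "Inflammation"),
        # three alternative 3-hop chains between SARS-CoV-2 and ACE2
        ("SARS-CoV-2", "(1,0)"), ("(1,0)", "(1,1)"), ("(1,1)", "ACE2"),
        ("SARS-CoV-2", "(2,0)"), ("(2,0)", "(2,1)"), ("(2,1)", "ACE2"),
        ("SARS-CoV-2", "(3,0)"), ("(3,0)", "(3,1)"), ("(3,1)", "ACE2"),
        # the 2-hop chain between AngII and Vascular Permeability
        ("AngII", "(1,0)'"), ("(1,0)'", "Vascular Permeability"),
    )
)

#: Entity sets of the two focal publications.
_WEX_PUB1_ENTITIES = frozenset(
    {"SARS-CoV-2", "(1,0)", "(1,1)", "ACE2", "AngII", "Hypertension", "Inflammation", "(1,0)'"}
)
_WEX_PUB2_ENTITIES = frozenset(
    {"(1,0)", "(1,1)", "ACE2", "AngII", "Hypertension", "Inflammation"}
)

_PAIR_DOCS_PER_EDGE = 3  # dedicated two-entity documents per designed edge
_TARGET_MARGINAL = 26  # document frequency every entity is brought up to


@dataclass
class WorkedExampleFixture:
    """The worked-example corpus plus its ground truth."""

    metadata: pd.DataFrame
    lexicon: Lexicon
    query: GraphQuery
    pub1_id: str
    pub2_id: str
    designed_edges: frozenset[tuple[str, str]]
    expected_addends_pub1: dict[tuple[str, str], float]
    expected_addends_pub2: dict[tuple[str, str], float]
    expected_score_pub1: float
    expected_score_pub2: float
    expected_selected_paths: dict[tuple[str, str], tuple[str, ...]]

    def run(self) -> PipelineResult:
        """Push the fixture abstracts through the full pipeline."""
        return run_pipeline(self.metadata, self.lexicon)


def worked_example_fixture() -> WorkedExampleFixture:
    """Build the worked search example.

    The query holds 6 concepts and 5 relationships. Three query edges
    exist in the network; SARS-CoV-2--ACE2 expands into 3 alternative
    paths of length 3 (the chain through "(1,0)" and "(1,1)" carries the
    highest average NPMI and is selected); AngII--Vascular Permeability
    expands into the single length-2 chain through "(1,0)'".

    Publication 1 mentions every selected-path edge except the tail
    "(1,0)'"--Vascular Permeability: addends (1, 1, 1, 1, 1/2), score
    4.5. Publication 2 lacks SARS-CoV-2 and "(1,0)'": it scores 2/3 on
    the SARS-CoV-2--ACE2 expansion, 0 on the AngII one, 1 elsewhere,
    total 11/3.

    Besides the two focal publications, the corpus holds dedicated
    two-entity documents boosting each designed edge's joint count and
    single-entity documents equalising every document frequency, so that
    exactly the designed edges survive the NPMI > 0 cut while every
    incidental pair co-occurring in the focal publications prunes away.
    """
    vocabulary = [
        LexiconTerm(
            surface_form=surface, concept_name=name, umls_id=umls,
            macrocategory=macro, semantic_type=sem,
        )
        for name, surface, umls, macro, sem in _WEX_CONCEPTS
    ]
    names = [t.concept_name for t in vocabulary]
    surface_of = {t.concept_name: t.surface_form for t in vocabulary}

    def doc_surfaces(entity_names) -> list[str]:
        return [surface_of[n] for n in names if n in entity_names]

    rows = []
    counter = 0

    def add_doc(record_id: str, entities) -> None:
        nonlocal counter
        day = date(2020, 1, 1) + timedelta(days=(counter * 7) % 1000)
        rows.append(_row(record_id, counter, _abstract_for(doc_surfaces(entities)), day.isoformat()))
        counter += 1

    add_doc("pub0001", _WEX_PUB1_ENTITIES)
    add_doc("pub0002", _WEX_PUB2_ENTITIES)
    for j, (a, b) in enumerate(_WEX_EDGES):
        for i in range(_PAIR_DOCS_PER_EDGE):
            add_doc(f"pair{j:02d}x{i}", {a, b})

    # bring every marginal document frequency up to the common target so
    # the NPMI discrimination between designed and incidental pairs is a
    # pure function of joint counts
    degree = {n: 0 for n in names}
    for a, b in _WEX_EDGES:
        degree[a] += 1
        degree[b] += 1
    for idx, name in enumerate(names):
        base = _PAIR_DOCS_PER_EDGE * degree[name]
        base += int(name in _WEX_PUB1_ENTITIES) + int(name in _WEX_PUB2_ENTITIES)
        n_singletons = _TARGET_MARGINAL - base
        assert n_singletons >= 0, name
        for i in range(n_singletons):
            add_doc(f"sing{idx:02d}x{i:02d}", {name})

    metadata = pd.DataFrame(rows)
    query = GraphQuery.from_lists(
        nodes=["SARS-CoV-2", "ACE2", "AngII", "Vascular Permeability", "Hypertension", "Inflammation"],
        edges=[
            ("SARS-CoV-2", "ACE2"),
            ("AngII", "Vascular Permeability"),
            ("ACE2", "AngII"),
            ("AngII", "Hypertension"),
            ("Hypertension", "Inflammation"),
        ],
    )

    e_sa = edge_key("SARS-CoV-2", "ACE2")
    e_gv = edge_key("AngII", "Vascular Permeability")
    e_ag = edge_key("ACE2", "AngII")
    e_gh = edge_key("AngII", "Hypertension")
    e_hi = edge_key("Hypertension", "Inflammation")
    return WorkedExampleFixture(
        metadata=metadata,
        lexicon=build_lexicon(vocabulary),
        query=query,
        pub1_id="pub0001",
        pub2_id="pub0002",
        designed_edges=frozenset(_WEX_EDGES),
        expected_addends_pub1={e_sa: 1.0, e_gv: 0.5, e_ag: 1.0, e_gh: 1.0, e_hi: 1.0},
        expected_addends_pub2={e_sa: 2.0 / 3.0, e_gv: 0.0, e_ag: 1.0, e_gh: 1.0, e_hi: 1.0},
        expected_score_pub1=4.5,
        expected_score_pub2=11.0 / 3.0,
        expected_selected_paths={
            # oriented from the alphabetically first endpoint of the query edge
            e_sa: ("ACE2", "(1,1)", "(1,0)", "SARS-CoV-2"),
            e_gv: ("AngII", "(1,0)'", "Vascular Permeability"),
        },
    )
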