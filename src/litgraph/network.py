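"""Co-occurrence network construction and association statistics.

Nodes are curated ontology concepts (plus utility terms); an undirected
edge links two concepts that are mentioned together in at least one
document. Each edge carries the joint document frequency and three
association measures computed from the 2x2 document contingency table:

* PMI   ``log p(x,y) / (p(x) p(y))`` — natural log by default;
* NPMI  ``pmi / (-log p(x,y))`` in [-1, 1], 0 at independence, 1 when
  the pair only ever occurs together (and, by limit, when the pair
  occurs in every document);
* Cramér's V ``sqrt(chi2 / N)`` on the 2x2 presence/absence table.

Edges with NPMI <= 0 express no positive association and are pruned;
the query engine then operates on the pruned graph. An inverted index
maps each surviving edge to the sorted posting list of documents that
co-mention its endpoints.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Separator used in displayed edge names ("X.name—Y.name").
DEFAULT_SEPARATOR = "—"  # em dash


@dataclass(frozen=True)
class ConceptEntity:
    """A network node: curated concept or utility term with its document frequency."""

    name: str
    umls_id: str | None = None
    cido_id: str | None = None
    macrocategory: str = "UTILITY"
    semantic_type: str | None = None
    frequency: int = 1

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError(f"entity {self.name!r} has frequency {self.frequency} < 1")


def edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair: endpoint names in alphabetical order."""
    if a == b:
        raise ValueError(f"self-loop on {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class CoOccurrenceEdge:
    """An undirected relationship between two co-occurring concepts.

    ``source < target`` alphabetically; statistics are ``None`` until
    :func:`edge_statistics` has been applied.
    """

    source: str
    target: str
    frequency: int
    pmi: float | None = None
    npmi: float | None = None
    cramers_v: float | None = None

    def __post_init__(self) -> None:
        if self.source >= self.target:
            raise ValueError(f"edge endpoints not sorted: {self.source!r} >= {self.target!r}")
        if self.frequency < 1:
            raise ValueError("edge frequency must be >= 1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)

    def name(self, separator: str = DEFAULT_SEPARATOR) -> str:
        return f"{self.source}{separator}{self.target}"


@dataclass
class CoOccurrenceNetwork:
    """The pruned co-occurrence graph plus its corpus size."""

    nodes: dict[str, ConceptEntity]
    edges: dict[tuple[str, str], CoOccurrenceEdge]
    corpus_size: int
    separator: str = DEFAULT_SEPARATOR

    def __post_init__(self) -> None:
        for key, edge in self.edges.items():
            if key != edge.key:
                raise ValueError(f"edge stored under wrong key {key}")
            for endpoint in key:
                if endpoint not in self.nodes:
                    raise ValueError(f"edge endpoint {endpoint!r} is not a node")

    def has_edge(self, a: str, b: str) -> bool:
        return edge_key(a, b) in self.edges

    def get_edge(self, a: str, b: str) -> CoOccurrenceEdge:
        return self.edges[edge_key(a, b)]

    def graph(self) -> nx.Graph:
        """The network as an undirected :class:`networkx.Graph` (npmi edge attr)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), e in self.edges.items():
            g.add_edge(a, b, npmi=e.npmi, frequency=e.frequency)
        return g


# ---------------------------------------------------------------------------
# link mining


def build_cooccurrences(doc_entities: Mapping[str, Iterable[str]]) -> dict[tuple[str, str], int]:
    """Count pairwise co-occurrence frequencies in one pass over the corpus.

    For every unordered concept pair mentioned together in at least one
    document, returns the number of documents containing both. Work is
    proportional to the sum over documents of ``k_d choose 2`` (k_d =
    entities in document d), not to the square of the vocabulary.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for _record_id, names in doc_entities.items():
        unique = sorted(set(names))
        for a, b in combinations(unique, 2):
            counts[(a, b)] += 1
    return dict(counts)


def edge_statistics(
    joint: int,
    freq_x: int,
    freq_y: int,
    corpus_size: int,
    log_base: float = math.e,
) -> tuple[float, float, float]:
    """PMI, NPMI and Cramér's V for one entity pair.

    Probabilities are document frequencies over ``corpus_size``. NPMI is
    independent of ``log_base`` (a ratio of logarithms); PMI scales with
    it. The degenerate case p(x,y) = 1 (the pair occurs in every
    document) has -log p(x,y) = 0 and NPMI is defined as 1 by limit.
    """
    n = corpus_size
    if freq_x < 1 or freq_y < 1:
        raise ValueError("marginal frequencies must be >= 1")
    if not 1 <= joint <= min(freq_x, freq_y) <= n:
        raise ValueError(
            f"inconsistent counts: joint={joint}, marginals=({freq_x}, {freq_y}), N={n}"
        )
    p_xy = joint / n
    log = lambda v: math.log(v) / math.log(log_base)  # noqa: E731
    pmi = log(p_xy / ((freq_x / n) * (freq_y / n)))
    if joint == n:
        logger.warning("pair occurs in every document; NPMI defined as 1 by limit")
        npmi = 1.0
    else:
        npmi = log(p_xy / ((freq_x / n) * (freq_y / n))) / (-log(p_xy))

    # 2x2 presence/absence table: a=both, b=x only, c=y only, d=neither
    a = joint
    b = freq_x - joint
    c = freq_y - joint
    d = n - freq_x - freq_y + joint
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        # a degenerate margin (entity in every/no document): association undefined
        cramers_v = 0.0
    else:
        chi2 = n * (a * d - b * c) ** 2 / denom
        cramers_v = math.sqrt(chi2 / n)
    return pmi, npmi, cramers_v


def attach_statistics(
    pair_counts: Mapping[tuple[str, str], int],
    entities: Mapping[str, ConceptEntity],
    corpus_size: int,
    log_base: float = math.e,
) -> list[CoOccurrenceEdge]:
    """Build fully annotated edges from raw pair counts and entity frequencies."""
    edges = []
    for (x, y), joint in sorted(pair_counts.items()):
        pmi, npmi, v = edge_statistics(
            joint, entities[x].frequency, entities[y].frequency, corpus_size, log_base
        )
        edges.append(
            CoOccurrenceEdge(source=x, target=y, frequency=joint, pmi=pmi, npmi=npmi, cramers_v=v)
        )
    return edges


def prune_edges(
    edges: Iterable[CoOccurrenceEdge], min_npmi: float = 0.0
) -> list[CoOccurrenceEdge]:
    """Keep only edges with NPMI strictly above ``min_npmi``.

    A non-positive NPMI means the pair co-occurs no more than expected
    under independence, so the default cut drops NPMI <= 0.
    """
    edges = list(edges)
    kept = [e for e in edges if e.npmi is not None and e.npmi > min_npmi]
    logger.info("prune_edges: kept %d of %d edges (npmi > %g)", len(kept), len(edges), min_npmi)
    return kept


def build_network(
    entity_table,
    corpus_size: int | None = None,
    min_npmi: float = 0.0,
    log_base: float = math.e,
    separator: str = DEFAULT_SEPARATOR,
) -> "CoOccurrenceNetwork":
    """Entity table -> statistics -> pruned network, in one call.

    ``corpus_size`` is the number of cleaned documents (N); documents
    mentioning no entity still count toward N and default detection
    from the entity table cannot see them, so pipelines should pass it.
    """
    if corpus_size is None:
        corpus_size = len(entity_table.doc_entities)
    pair_counts = build_cooccurrences(entity_table.doc_entities)
    edges = attach_statistics(pair_counts, entity_table.entities, corpus_size, log_base)
    pruned = prune_edges(edges, min_npmi)
    return CoOccurrenceNetwork(
        nodes=dict(entity_table.entities),
        edges={e.key: e for e in pruned},
        corpus_size=corpus_size,
        separator=separator,
    )


# ---------------------------------------------------------------------------
# connectivity


@dataclass(frozen=True)
class ConnectivityReport:
    component_count: int
    sizes: tuple[int, ...]  # descending
    is_single_component: bool
    warning: str | None = None


def connectivity_report(network: CoOccurrenceNetwork) -> ConnectivityReport:
    """Connected components of the pruned graph (isolated nodes included).

    A single connected component guarantees that every connected graph
    query over known nodes can be matched by path expansion; searching a
    fragmented network is allowed but some expansions may come back
    empty, hence the warning.
    """
    components = list(nx.connected_components(network.graph()))
    sizes = tuple(sorted((len(c) for c in components), reverse=True))
    single = len(components) <= 1
    warning = None
    if not single:
        warning = (
            f"network has {len(components)} connected components; "
            "queries spanning components will produce empty expansions"
        )
        logger.warning(warning)
    return ConnectivityReport(
        component_count=len(components),
        sizes=sizes,
        is_single_component=single,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# inverted index


@dataclass
class InvertedIndex:
    """Posting lists keyed by network edge.

    Keys are canonical endpoint pairs (never re-parsed from display
    names, which may themselves contain the separator); each posting
    list is the sorted, duplicate-free list of record ids whose
    documents mention both endpoints.
    """

    postings: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    separator: str = DEFAULT_SEPARATOR

    def get(self, a: str, b: str) -> list[str]:
        key = edge_key(a, b)
        lst = self.postings.get(key)
        if lst is None:
            logger.debug("inverted index miss for %s", key)
            return []
        return lst

    def __len__(self) -> int:
        return len(self.postings)


def build_inverted_index(
    edges: Iterable[CoOccurrenceEdge],
    doc_entities: Mapping[str, Iterable[str]],
    separator: str = DEFAULT_SEPARATOR,
) -> InvertedIndex:
    """Posting lists for the (pruned) edge set.

    ``|postings[e]| == e.frequency`` for every edge by construction.
    """
    wanted = {e.key for e in edges}
    postings: dict[tuple[str, str], list[str]] = {k: [] for k in wanted}
    for record_id in sorted(doc_entities):
        unique = sorted(set(doc_entities[record_id]))
        for pair in combinations(unique, 2):
            if pair in postings:
                postings[pair].append(record_id)
    return InvertedIndex(postings=postings, separator=separator)


# ---------------------------------------------------------------------------
# serialization (portable flat files; no graph-database dependency)

NODES_COLUMNS = ("name", "umls_id", "cido_id", "macrocategory", "type", "frequency")
EDGES_COLUMNS = ("name_x", "name_y", "frequency", "pmi", "npmi", "cramers_v")


def save_network(network: CoOccurrenceNetwork, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        [
            {
                "name": e.name,
                "umls_id": e.umls_id or "",
                "cido_id": e.cido_id or "",
                "macrocategory": e.macrocategory,
                "type": e.semantic_type or "",
                "frequency": e.frequency,
            }
            for e in sorted(network.nodes.values(), key=lambda e: e.name)
        ],
        columns=NODES_COLUMNS,
    )
    nodes.to_csv(directory / "nodes.tsv", sep="\t", index=False)
    edges = pd.DataFrame(
        [
            {
                "name_x": e.source,
                "name_y": e.target,
                "frequency": e.frequency,
                "pmi": repr(e.pmi),
                "npmi": repr(e.npmi),
                "cramers_v": repr(e.cramers_v),
            }
            for e in sorted(network.edges.values(), key=lambda e: e.key)
        ],
        columns=EDGES_COLUMNS,
    )
    edges.to_csv(directory / "edges.tsv", sep="\t", index=False)
    meta = {"corpus_size": network.corpus_size, "separator": network.separator}
    (directory / "meta.json").write_text(json.dumps(meta, sort_keys=True) + "\n", encoding="utf-8")


def load_network(directory: str | Path) -> CoOccurrenceNetwork:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
    nodes_df = pd.read_csv(directory / "nodes.tsv", sep="\t", dtype=str, keep_default_na=False)
    nodes = {}
    for row in nodes_df.to_dict("records"):
        nodes[row["name"]] = ConceptEntity(
            name=row["name"],
            umls_id=row["umls_id"] or None,
            cido_id=row["cido_id"] or None,
            macrocategory=row["macrocategory"],
            semantic_type=row["type"] or None,
            frequency=int(row["frequency"]),
        )
    edges_df = pd.read_csv(directory / "edges.tsv", sep="\t", dtype=str, keep_default_na=False)
    edges = {}
    for row in edges_df.to_dict("records"):
        e = CoOccurrenceEdge(
            source=row["name_x"],
            target=row["name_y"],
            frequency=int(row["frequency"]),
            pmi=float(row["pmi"]),
            npmi=float(row["npmi"]),
            cramers_v=float(row["cramers_v"]),
        )
        edges[e.key] = e
    return CoOccurrenceNetwork(
        nodes=nodes,
        edges=edges,
        corpus_size=int(meta["corpus_size"]),
        separator=meta.get("separator", DEFAULT_SEPARATOR),
    )


def save_index(index: InvertedIndex, path: str | Path) -> None:
    """JSON-lines: one record per edge with its display name and postings."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for (a, b) in sorted(index.postings):
            fh.write(
                json.dumps(
                    {
                        "x": a,
                        "y": b,
                        "name": f"{a}{index.separator}{b}",
                        "postings": index.postings[(a, b)],
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def load_index(path: str | Path, separator: str = DEFAULT_SEPARATOR) -> InvertedIndex:
    postings = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            postings[(rec["x"], rec["y"])] = list(rec["postings"])
    return InvertedIndex(postings=postings, separator=separator)
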