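"""Graph-query matching, path expansion, and publication ranking.

A *graph query* Q is a small connected undirected graph whose nodes are
concepts of the co-occurrence network and whose edges are relationships
the user asserts between them. Matching Q against the network N is an
inexact-matching problem: every node of Q resolves to a node of N, but a
query edge need not exist in N. Each missing edge is *expanded* into the
set of minimal-hop simple paths between its endpoints; candidates are
ranked by the average NPMI of their edges and the top 10 are retained.
The user (or the default top-rank rule) selects one path per expansion.

Publications are then retrieved through the inverted index and scored by
the number of *explained relationships*:

    score(P, Q) = sum over r in rels(Q) of  m_r / len(path(r))

where ``m_r`` is the number of edges of the selected path for r whose
posting list contains P. Each addend lies in [0, 1]; it is 1 when P
mentions the whole path (in particular when r itself is a network edge
P mentions) and 0 when P mentions none of it or the expansion is empty.
Results are ranked by (score, NPMI sum over distinct mentioned edges,
publication date, record id).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .corpus import PublicationRecord, normalized_similarity
from .network import CoOccurrenceNetwork, InvertedIndex, edge_key

logger = logging.getLogger(__name__)

DEFAULT_MAX_CANDIDATES = 10


class QueryError(ValueError):
    """Base class for query validation problems."""


class NodeResolutionError(QueryError):
    """A query node does not exist in the network."""

    def __init__(self, name: str, suggestions: Sequence[str]):
        self.name = name
        self.suggestions = list(suggestions)
        hint = f"; did you mean: {', '.join(self.suggestions)}?" if self.suggestions else ""
        super().__init__(f"query node {name!r} not found in the network{hint}")


class DisconnectedQueryError(QueryError):
    def __init__(self, components: Sequence[frozenset[str]]):
        self.components = list(components)
        parts = "; ".join(sorted("{" + ", ".join(sorted(c)) + "}" for c in components))
        super().__init__(f"graph query is not connected: components {parts}")


@dataclass(frozen=True)
class GraphQuery:
    """A user query: entity names plus unordered relationships over them."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_lists(cls, nodes: Iterable[str], edges: Iterable[Sequence[str]]) -> "GraphQuery":
        node_set = frozenset(nodes)
        edge_set = frozenset(edge_key(a, b) for a, b in edges)
        return cls(nodes=node_set, edges=edge_set)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)


@dataclass(frozen=True)
class PathCandidate:
    """One minimal-hop simple path substituting for a query edge."""

    source: str
    target: str
    nodes: tuple[str, ...]  # source .. target inclusive
    edges: tuple[tuple[str, str], ...]
    avg_npmi: float

    @property
    def length(self) -> int:
        return len(self.edges)


@dataclass
class Expansion:
    """All retained candidate paths for one query edge, plus the selection."""

    query_edge: tuple[str, str]
    candidates: list[PathCandidate]
    selected: int = 0

    @property
    def selected_path(self) -> PathCandidate | None:
        if not self.candidates:
            return None
        return self.candidates[self.selected]

    def select(self, rank: int) -> None:
        if not 0 <= rank < len(self.candidates):
            raise IndexError(
                f"candidate rank {rank} out of range for expansion {self.query_edge} "
                f"({len(self.candidates)} candidates)"
            )
        self.selected = rank


@dataclass(frozen=True)
class ScoredPublication:
    """A retrieved publication with its explained-relationship score."""

    record_id: str
    score: float
    npmi_sum: float
    addends: tuple[tuple[tuple[str, str], float], ...]
    publish_time: date | None = None
    num_cited_by: int | None = None

    def addends_dict(self) -> dict[tuple[str, str], float]:
        return dict(self.addends)


# ---------------------------------------------------------------------------
# validation


def validate_query(query: GraphQuery, network: CoOccurrenceNetwork) -> GraphQuery:
    """Check node resolution, self-loops, and connectivity.

    Unknown nodes raise :class:`NodeResolutionError` carrying up to five
    near-matches by normalized Levenshtein similarity; a disconnected
    query raises :class:`DisconnectedQueryError` naming the components.
    Returns the query with edges in canonical sorted form.
    """
    if not query.nodes:
        raise QueryError("query has no nodes")
    for name in sorted(query.nodes):
        if name not in network.nodes:
            scored = sorted(
                ((normalized_similarity(name.casefold(), cand.casefold()), cand)
                 for cand in network.nodes),
                key=lambda t: (-t[0], t[1]),
            )
            suggestions = [cand for sim, cand in scored[:5] if sim >= 0.5]
            raise NodeResolutionError(name, suggestions)
    for a, b in query.edges:
        if a == b:
            raise QueryError(f"self-loop on query node {a!r}")
        if a not in query.nodes or b not in query.nodes:
            raise QueryError(f"edge ({a!r}, {b!r}) references a node missing from the query")
    g = nx.Graph()
    g.add_nodes_from(query.nodes)
    g.add_edges_from(query.edges)
    components = [frozenset(c) for c in nx.connected_components(g)]
    if len(components) > 1:
        raise DisconnectedQueryError(components)
    return GraphQuery(nodes=query.nodes, edges=frozenset(edge_key(a, b) for a, b in query.edges))


# ---------------------------------------------------------------------------
# expansion


def find_path_candidates(
    network: CoOccurrenceNetwork,
    source: str,
    target: str,
    k: int = DEFAULT_MAX_CANDIDATES,
    graph: nx.Graph | None = None,
) -> list[PathCandidate]:
    """Top-``k`` minimal-hop simple paths between two network nodes.

    Path length is the number of edges (unweighted hops); *all* paths of
    the minimal length are enumerated, ranked by mean NPMI (descending,
    ties broken by the lexicographic node sequence) and truncated to
    ``k``. A query edge already present in the network yields exactly
    its own length-1 path. Returns an empty list when no path exists
    (fragmented network), which downstream scores as 0.
    """
    if source == target:
        raise QueryError("path endpoints must differ")
    if network.has_edge(source, target):
        key = edge_key(source, target)
        npmi = network.edges[key].npmi or 0.0
        return [
            PathCandidate(
                source=source, target=target, nodes=(source, target),
                edges=(key,), avg_npmi=npmi,
            )
        ]
    g = graph if graph is not None else network.graph()
    try:
        raw_paths = list(nx.all_shortest_paths(g, source, target))
    except nx.NetworkXNoPath:
        logger.warning("no path between %r and %r; expansion is empty", source, target)
        return []
    candidates = []
    for nodes in raw_paths:
        edges = tuple(edge_key(a, b) for a, b in zip(nodes, nodes[1:]))
        npmis = [network.edges[e].npmi or 0.0 for e in edges]
        candidates.append(
            PathCandidate(
                source=source,
                target=target,
                nodes=tuple(nodes),
                edges=edges,
                avg_npmi=sum(npmis) / len(npmis),
            )
        )
    candidates.sort(key=lambda c: (-c.avg_npmi, c.nodes))
    return candidates[:k]


def expand_query(
    query: GraphQuery,
    network: CoOccurrenceNetwork,
    k: int = DEFAULT_MAX_CANDIDATES,
    selections: Mapping[tuple[str, str], int] | None = None,
) -> list[Expansion]:
    """One :class:`Expansion` per query edge, in sorted edge order.

    ``selections`` optionally overrides the default top-NPMI choice with
    a candidate rank per query edge.
    """
    g = network.graph()
    expansions = []
    for qe in query.sorted_edges():
        exp = Expansion(query_edge=qe, candidates=find_path_candidates(network, *qe, k=k, graph=g))
        if selections and qe in selections and exp.candidates:
            exp.select(selections[qe])
        expansions.append(exp)
    return expansions


# ---------------------------------------------------------------------------
# scoring and ranking


def score_publication(
    record_id: str,
    expansions: Sequence[Expansion],
    index: InvertedIndex,
    npmi_lookup: Mapping[tuple[str, str], float] | None = None,
) -> ScoredPublication:
    """Explained-relationship score of one publication.

    Per expansion with a selected path of length L mentioning m of its
    edges in ``record_id``'s postings, the addend is m / L; empty
    expansions contribute 0. ``npmi_sum`` accumulates the NPMI of every
    *distinct* network edge mentioned across the selected paths
    (``npmi_lookup`` maps edge keys to NPMI; without it the sum is 0).
    """
    addends: list[tuple[tuple[str, str], float]] = []
    mentioned: set[tuple[str, str]] = set()
    npmi_by_edge: dict[tuple[str, str], float] = dict(npmi_lookup or {})
    for exp in expansions:
        path = exp.selected_path
        if path is None:
            addends.append((exp.query_edge, 0.0))
            continue
        m = 0
        for e in path.edges:
            if record_id in index.postings.get(e, ()):  # posting lists are sorted & small
                m += 1
                mentioned.add(e)
        addends.append((exp.query_edge, m / path.length))
    return ScoredPublication(
        record_id=record_id,
        score=sum(a for _, a in addends),
        npmi_sum=sum(npmi_by_edge.get(e, 0.0) for e in mentioned),
        addends=tuple(addends),
    )


def retrieve_and_rank(
    expansions: Sequence[Expansion],
    index: InvertedIndex,
    metadata: Mapping[str, PublicationRecord] | None = None,
    network: CoOccurrenceNetwork | None = None,
    top: int | None = None,
    rank_by: str = "relevance",
    newest_first: bool = True,
) -> list[ScoredPublication]:
    """Retrieve and rank the publications touched by the selected paths.

    The candidate set is the *union* of the posting lists of all
    selected-path edges (so partially explaining publications surface).
    Ranking keys: (1) explained-relationship score, (2) NPMI sum,
    (3) publication date (most recent first by default), then record id
    for a total order. ``rank_by="citations"`` re-sorts by citation
    count first.
    """
    if rank_by not in ("relevance", "citations"):
        raise ValueError(f"unknown rank_by {rank_by!r}")
    npmi_lookup: dict[tuple[str, str], float] = {}
    if network is not None:
        npmi_lookup = {k: (e.npmi or 0.0) for k, e in network.edges.items()}
    candidate_ids: set[str] = set()
    path_edges: set[tuple[str, str]] = set()
    for exp in expansions:
        path = exp.selected_path
        if path is None:
            continue
        for e in path.edges:
            path_edges.add(e)
            candidate_ids.update(index.postings.get(e, ()))

    scored = []
    for record_id in sorted(candidate_ids):
        pub = score_publication(record_id, expansions, index, npmi_lookup=npmi_lookup)
        record = metadata.get(record_id) if metadata else None
        scored.append(
            replace(
                pub,
                publish_time=record.publish_time if record else None,
                num_cited_by=record.num_cited_by if record else None,
            )
        )

    def date_ord(p: ScoredPublication) -> int:
        d = p.publish_time or date.min
        sign = -1 if newest_first else 1
        return sign * d.toordinal()

    if rank_by == "citations":
        key = lambda p: (-(p.num_cited_by or 0), -p.score, -p.npmi_sum, date_ord(p), p.record_id)  # noqa: E731
    else:
        key = lambda p: (-p.score, -p.npmi_sum, date_ord(p), p.record_id)  # noqa: E731
    scored.sort(key=key)
    if top is not None:
        scored = scored[:top]
    return scored


def search(
    query: GraphQuery,
    network: CoOccurrenceNetwork,
    index: InvertedIndex,
    metadata: Mapping[str, PublicationRecord] | None = None,
    k: int = DEFAULT_MAX_CANDIDATES,
    selections: Mapping[tuple[str, str], int] | None = None,
    top: int | None = None,
    rank_by: str = "relevance",
) -> tuple[list[Expansion], list[ScoredPublication]]:
    """Validate, expand, retrieve and rank in one call."""
    query = validate_query(query, network)
    expansions = expand_query(query, network, k=k, selections=selections)
    results = retrieve_and_rank(
        expansions, index, metadata=metadata, network=network, top=top, rank_by=rank_by
    )
    return expansions, results


# ---------------------------------------------------------------------------
# query file format


def load_query(path: str | Path) -> tuple[GraphQuery, dict[tuple[str, str], int]]:
    """Read a query JSON file: ``nodes``, ``edges``, optional ``selections``.

    ``selections`` maps "A|B" edge labels to candidate ranks.
    """
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    query = GraphQuery.from_lists(payload["nodes"], [tuple(e) for e in payload["edges"]])
    selections = {}
    for label, rank in (payload.get("selections") or {}).items():
        a, b = label.split("|", 1)
        selections[edge_key(a, b)] = int(rank)
    return query, selections


def save_query(
    query: GraphQuery,
    path: str | Path,
    selections: Mapping[tuple[str, str], int] | None = None,
) -> None:
    payload = {
        "nodes": sorted(query.nodes),
        "edges": [list(e) for e in query.sorted_edges()],
    }
    if selections:
        payload["selections"] = {f"{a}|{b}": rank for (a, b), rank in sorted(selections.items())}
    Path(path).write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
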