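"""Query validation, shortest-path expansion, scoring and ranking."""

from datetime import date
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litgraph.corpus import PublicationRecord
from litgraph.network import (
    ConceptEntity,
    CoOccurrenceEdge,
    CoOccurrenceNetwork,
    InvertedIndex,
    edge_key,
)
from litgraph.query import (
    DisconnectedQueryError,
    Expansion,
    GraphQuery,
    NodeResolutionError,
    PathCandidate,
    expand_query,
    find_path_candidates,
    retrieve_and_rank,
    score_publication,
    validate_query,
)


def make_network(weighted_edges, nodes=None):
    """weighted_edges: iterable of (a, b, npmi)."""
    nodes = set(nodes or [])
    edges = {}
    for a, b, npmi in weighted_edges:
        key = edge_key(a, b)
        nodes.update(key)
        edges[key] = CoOccurrenceEdge(source=key[0], target=key[1], frequency=1,
                                      pmi=npmi, npmi=npmi, cramers_v=0.1)
    return CoOccurrenceNetwork(
        nodes={n: ConceptEntity(name=n, frequency=1) for n in sorted(nodes)},
        edges=edges,
        corpus_size=100,
    )


class TestValidateQuery:
    def test_minimal_two_node_query(self):
        net = make_network([("A", "B", 0.5)])
        q = validate_query(GraphQuery.from_lists(["A", "B"], [("A", "B")]), net)
        assert q.sorted_edges() == [("A", "B")]

    def test_unknown_node_suggests_near_matches(self):
        net = make_network([("Myocarditis", "COVID-19", 0.5)])
        with pytest.raises(NodeResolutionError) as exc:
            validate_query(GraphQuery.from_lists(["Myocardits", "COVID-19"],
                                                 [("Myocardits", "COVID-19")]), net)
        assert "Myocarditis" in exc.value.suggestions

    def test_disconnected_query_rejected(self):
        net = make_network([("A", "B", 0.5), ("C", "D", 0.5), ("B", "C", 0.5)])
        with pytest.raises(DisconnectedQueryError):
            validate_query(
                GraphQuery.from_lists(["A", "B", "C", "D"], [("A", "B"), ("C", "D")]), net
            )

    def test_self_loop_rejected(self):
        # rejected at edge construction, before validation even starts
        with pytest.raises(ValueError):
            GraphQuery.from_lists(["A"], [("A", "A")])


class TestFindPathCandidates:
    def test_shortest_alternative_wins(self):
        # A-X-B beats A-Y-Z-B and A-V-Y-Z-B: hop count defines length
        net = make_network(
            [("A", "X", 0.1), ("X", "B", 0.1),
             ("A", "Y", 0.9), ("Y", "Z", 0.9), ("Z", "B", 0.9),
             ("A", "V", 0.9), ("V", "Y", 0.9)]
        )
        candidates = find_path_candidates(net, "A", "B")
        assert len(candidates) == 1
        assert candidates[0].nodes == ("A", "X", "B")
        assert candidates[0].length == 2

    def test_direct_edge_needs_no_expansion(self):
        net = make_network([("A", "B", 0.3), ("A", "X", 0.9), ("X", "B", 0.9)])
        candidates = find_path_candidates(net, "A", "B")
        assert len(candidates) == 1
        assert candidates[0].edges == (("A", "B"),)
        assert candidates[0].avg_npmi == pytest.approx(0.3)

    def test_top_10_of_15_equal_length_paths(self):
        # 15 distinct 2-hop paths A-Mi-B with distinct average NPMI
        edges = []
        for i in range(15):
            npmi = 0.05 + i * 0.06
            edges += [("A", f"M{i:02d}", npmi), (f"M{i:02d}", "B", npmi)]
        net = make_network(edges)
        candidates = find_path_candidates(net, "A", "B", k=10)
        assert len(candidates) == 10
        avgs = [c.avg_npmi for c in candidates]
        assert avgs == sorted(avgs, reverse=True)
        assert candidates[0].nodes == ("A", "M14", "B")

    def test_no_path_gives_empty_expansion(self):
        net = make_network([("A", "B", 0.5), ("C", "D", 0.5)])
        assert find_path_candidates(net, "A", "C") == []

    def test_avg_npmi_tie_broken_lexicographically(self):
        net = make_network(
            [("A", "P", 0.4), ("P", "B", 0.4), ("A", "Q", 0.4), ("Q", "B", 0.4)]
        )
        candidates = find_path_candidates(net, "A", "B")
        assert [c.nodes for c in candidates] == [("A", "P", "B"), ("A", "Q", "B")]

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 2**32 - 1))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        p = float(rng.uniform(0.08, 0.35))
        names = [f"n{i:02d}" for i in range(n)]
        edges = [
            (a, b, float(rng.uniform(0.01, 1.0)))
            for a, b in combinations(names, 2)
            if rng.random() < p
        ]
        net = make_network(edges, nodes=names)
        g = net.graph()
        for source, target in combinations(names, 2):
            got = find_path_candidates(net, source, target, k=10**9)
            if not nx.has_path(g, source, target):
                assert got == []
                continue
            d = nx.shortest_path_length(g, source, target)
            expected = {
                tuple(pth)
                for pth in nx.all_simple_paths(g, source, target, cutoff=d)
                if len(pth) == d + 1
            }
            assert {c.nodes for c in got} == expected
            assert all(c.length == d for c in got)
            avgs = [round(c.avg_npmi, 12) for c in got]
            assert avgs == sorted(avgs, reverse=True)


def expansion(qe, paths, selected=0):
    """paths: list of node tuples."""
    candidates = []
    for nodes in paths:
        edges = tuple(edge_key(a, b) for a, b in zip(nodes, nodes[1:]))
        candidates.append(PathCandidate(nodes[0], nodes[-1], tuple(nodes), edges, 0.5))
    return Expansion(query_edge=edge_key(*qe), candidates=candidates, selected=selected)


class TestScorePublication:
    def test_half_explained_two_edge_path(self):
        exp = expansion(("AngII", "Vascular Permeability"),
                        [("AngII", "M", "Vascular Permeability")])
        index = InvertedIndex(postings={edge_key("AngII", "M"): ["p1"],
                                        edge_key("M", "Vascular Permeability"): []})
        pub = score_publication("p1", [exp], index)
        assert pub.score == pytest.approx(0.5)

    def test_two_thirds_explained_three_edge_path(self):
        exp = expansion(("S", "A"), [("S", "u", "v", "A")])
        index = InvertedIndex(postings={edge_key("S", "u"): [],
                                        edge_key("u", "v"): ["p2"],
                                        edge_key("v", "A"): ["p2"]})
        assert score_publication("p2", [exp], index).score == pytest.approx(2 / 3)

    def test_full_query_explained_scores_edge_count(self):
        expansions = [expansion((f"X{i}", f"Y{i}"), [(f"X{i}", f"Y{i}")]) for i in range(5)]
        postings = {edge_key(f"X{i}", f"Y{i}"): ["p"] for i in range(5)}
        pub = score_publication("p", expansions, InvertedIndex(postings=postings))
        assert pub.score == 5.0
        assert all(a == 1.0 for _, a in pub.addends)

    def test_empty_expansion_contributes_zero(self):
        empty = Expansion(query_edge=("A", "B"), candidates=[])
        pub = score_publication("p", [empty], InvertedIndex(postings={}))
        assert pub.score == 0.0
        assert pub.addends == ((("A", "B"), 0.0),)

    def test_direct_edges_give_binary_addends(self):
        expansions = [expansion(("A", "B"), [("A", "B")]),
                      expansion(("B", "C"), [("B", "C")])]
        index = InvertedIndex(postings={("A", "B"): ["p"], ("B", "C"): []})
        pub = score_publication("p", expansions, index)
        assert {a for _, a in pub.addends} <= {0.0, 1.0}
        assert pub.score == 1.0

    def test_score_monotone_in_posting_membership(self):
        exp = expansion(("S", "A"), [("S", "u", "v", "A")])
        postings = {edge_key("S", "u"): ["p"], edge_key("u", "v"): [], edge_key("v", "A"): []}
        before = score_publication("p", [exp], InvertedIndex(postings=dict(postings))).score
        postings[edge_key("u", "v")] = ["p"]
        after = score_publication("p", [exp], InvertedIndex(postings=postings)).score
        assert after >= before


class TestRetrieveAndRank:
    def make_setup(self):
        net = make_network([("A", "B", 0.6), ("B", "C", 0.4)])
        index = InvertedIndex(postings={("A", "B"): ["p1", "p2"], ("B", "C"): ["p1"]})
        q = GraphQuery.from_lists(["A", "B", "C"], [("A", "B"), ("B", "C")])
        expansions = expand_query(q, net)
        return net, index, expansions

    def test_candidate_set_is_union_of_postings(self):
        net, index, expansions = self.make_setup()
        results = retrieve_and_rank(expansions, index, network=net)
        assert [p.record_id for p in results] == ["p1", "p2"]
        assert results[0].score == 2.0 and results[1].score == 1.0
        assert results[0].npmi_sum == pytest.approx(1.0)

    def test_publication_in_no_posting_list_absent(self):
        net, index, expansions = self.make_setup()
        ids = {p.record_id for p in retrieve_and_rank(expansions, index, network=net)}
        assert "p3" not in ids

    def test_date_breaks_exact_ties_newest_first(self):
        net, _, expansions = self.make_setup()
        index = InvertedIndex(postings={("A", "B"): ["new", "old"], ("B", "C"): []})
        metadata = {
            "old": PublicationRecord("old", "t", "a", publish_time=date(2020, 5, 1)),
            "new": PublicationRecord("new", "t", "a", publish_time=date(2021, 5, 1)),
        }
        results = retrieve_and_rank(expansions, index, metadata=metadata, network=net)
        assert [p.record_id for p in results] == ["new", "old"]

    def test_citation_ranking_option(self):
        net, _, expansions = self.make_setup()
        index = InvertedIndex(postings={("A", "B"): ["few", "many"], ("B", "C"): ["few"]})
        metadata = {
            "few": PublicationRecord("few", "t", "a", num_cited_by=1),
            "many": PublicationRecord("many", "t", "a", num_cited_by=50),
        }
        by_relevance = retrieve_and_rank(expansions, index, metadata=metadata, network=net)
        by_citations = retrieve_and_rank(
            expansions, index, metadata=metadata, network=net, rank_by="citations"
        )
        assert [p.record_id for p in by_relevance] == ["few", "many"]
        assert [p.record_id for p in by_citations] == ["many", "few"]

    def test_ranking_is_deterministic(self):
        net, index, expansions = self.make_setup()
        a = retrieve_and_rank(expansions, index, network=net)
        b = retrieve_and_rank(expansions, index, network=net)
        assert a == b


class TestExpandQuery:
    def test_expansion_per_edge_with_selection_override(self):
        net = make_network(
            [("A", "P", 0.9), ("P", "B", 0.9), ("A", "Q", 0.2), ("Q", "B", 0.2)]
        )
        q = GraphQuery.from_lists(["A", "B"], [("A", "B")])
        (exp,) = expand_query(q, net)
        assert exp.selected_path.nodes == ("A", "P", "B")
        exp.select(1)
        assert exp.selected_path.nodes == ("A", "Q", "B")
        with pytest.raises(IndexError):
            exp.select(5)

    def test_all_direct_query_has_single_candidates(self):
        net = make_network([("A", "B", 0.5), ("B", "C", 0.5), ("A", "X", 0.9), ("X", "B", 0.9)])
        q = GraphQuery.from_lists(["A", "B", "C"], [("A", "B"), ("B", "C")])
        expansions = expand_query(q, net)
        assert all(len(e.candidates) == 1 and e.candidates[0].length == 1 for e in expansions)
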