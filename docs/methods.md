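# Methods

## Model

`litgraph` treats a corpus of publication records as a bag of documents
and a document as a *set* of ontology concepts mentioned in its title
and abstract. The co-occurrence network is the undirected graph over
those concepts in which an edge records that two concepts appear in the
same document at least once. All association statistics are computed
from document-level presence/absence counts over the cleaned corpus of
size N:

- p(x) = (documents mentioning x) / N, p(x,y) likewise for both;
- PMI(x,y) = log [ p(x,y) / (p(x) p(y)) ];
- NPMI(x,y) = PMI / (−log p(x,y)), in [−1, 1]: 0 at independence,
  1 when the two concepts only ever occur together (p(x,y) = p(x) =
  p(y) < 1), −1 as joint occurrence vanishes relative to the marginals;
- Cramér's V = √(χ²/N) with Pearson's χ² (no continuity correction) on
  the 2×2 table {both, x-only, y-only, neither}. On a 2×2 table
  min(r−1, c−1) = 1, so the usual denominator reduces to N.

A concept mentioned five times in one abstract counts once: frequency is
defined as the number of documents capturing the concept, and
co-occurrence likewise. Relationship direction and semantics are out of
scope — edges mean "co-mentioned", nothing more; semantics enters only
through node annotation (ontology ids, macrocategories, types).

Edges with NPMI ≤ 0 are excluded (strict inequality is required to
survive): a non-positive NPMI means the pair co-occurs at or below its
independence expectation. Cramér's V is computed and stored for every
edge but is not used by the query engine, which ranks by NPMI alone.

## Query matching and scoring

A graph query Q must be connected, self-loop-free, and name only
concepts present in the network. Matching is inexact on edges only: a
query edge absent from the network is expanded into candidate paths.

- **Path length is the hop count** (number of edges). One figure
  convention counts intermediate nodes instead, which is the same
  ordering shifted by one; hop count is used consistently here.
- All simple paths of the *minimal* hop length are enumerated (BFS level
  graph via `networkx.all_shortest_paths`); no longer paths are ever
  added, even when fewer than 10 minimal paths exist.
- Candidates are ranked by mean NPMI of their edges, descending; exact
  ties are broken by the lexicographic node-name sequence so the ranking
  is total and reproducible. The top 10 are retained.
- A query edge present in the network yields exactly its own length-1
  path: nothing shorter exists and no alternative is needed.
- One path per expansion is *selected* — rank 0 by default, overridable
  per edge (the relevance of a path is domain-specific and ultimately a
  user judgement).

For a publication P, each query edge r with selected path of length L
contributes m/L to score(P, Q), where m is the number of path edges
whose posting list contains P; an empty expansion (fragmented network)
contributes 0. The candidate set for retrieval is the **union** of the
posting lists of all selected-path edges — an intersection would hide
exactly the partially-explaining publications the fractional addends
exist to surface. The NPMI sum reported alongside the score counts each
distinct network edge once, even if two expansions share it. Ranking is
by (score desc, NPMI sum desc, date desc, record id asc); the date tier
prefers recent work, matching literature-search convention, and can be
reversed; ranking by citation count (when a citation column was
supplied) is available as an alternative first key.

## Corpus cleaning

Records must have a non-empty abstract. Titles are screened by a
pluggable English-language predicate; the default is a heuristic (ASCII
ratio ≥ 0.85, plus at least one English stopword for texts of ≥ 6
tokens) chosen to be dependency-free and deterministic, not a trained
detector. Dates parse as full ISO dates or fall back to a 4-digit year
stored as January 1 with a `date_precision = year` marker; a date field
that yields neither drops the record with a warning. Records dated
before `min_year` (default 2020) whose title *or* abstract contains an
exclusion term (default: the MERS/SARS/coronavirus family) are dropped —
applying the filter to both fields is the conservative reading and both
the field set and the term list are flags. Within a duplicate record-id
cluster exactly one row survives: a peer-reviewed row (journal present)
wins; otherwise the row with the most non-null values among {title,
abstract, publish_time, journal, authors, doi, num_cited_by}; remaining
ties keep the earliest row, so cleaning is order-stable and idempotent.

## Entity linking and curation

The default annotator is a dictionary matcher: text and lexicon surfaces
are NFKC-normalized, case-folded, stopword-filtered and plural-stripped
(a deliberately weak lemmatizer that never merges distinct concepts);
candidate n-grams are matched longest-first without overlap, so "cystic
fibrosis" yields one 2-gram mention rather than a 1-gram "fibrosis".
Any callable producing the same mention records can replace it — the
statistical NER models used in production-scale systems plug in here.

Each mention's similarity is 1 − d/max(|a|,|b|) with d the Levenshtein
distance (computed by `edlib`) between the raw matched span and the
lexicon surface; exact hits score 1. Similarity is computed on the raw
span rather than the lemmatized one (configurable): the threshold is
meant to measure surface fidelity, and lemmatization would hide
inflection distance. Mentions below the 0.7 threshold are discarded;
the cut is inclusive (0.70 survives) since the stated threshold is a
value to be met. Utility terms bypass the gate — they are exact
dictionary hits by construction.

## Synthetic corpora

The generators emulate only what the pipeline consumes: metadata rows
whose abstracts are bags of lexicon surfaces glued by filler stopwords.
`generate_corpus` plants entity pairs with specified joint probabilities
plus independent baseline mentions, fully determined by a seed; planted
joint frequencies converge on their expectations binomially. The worked
example (`worked_example_fixture`) is deterministic: beyond the two focal
publications it adds three dedicated two-entity documents per designed
edge and enough single-entity documents to equalise every marginal
document frequency at 26 over N = 284 documents. With equal marginals
F = 26, a pair needs joint count j with jN > F² to survive pruning:
designed edges have j ≥ 3 (852 > 676) while incidental pairs arising
inside the focal publications have j ≤ 2 (568 ≤ 676), so exactly the
designed 14-edge topology survives — the fixture's addends (1/2, 2/3)
and totals (4.5 vs 11/3) then follow from the scoring definition alone.

What these corpora do *not* emulate: real mention noise (misspellings,
ambiguous surfaces, NER errors), realistic frequency distributions
(Zipfian vocabularies, bursty topics), non-English text, or corpus
scale. Passing tests therefore demonstrate the correctness of the
pipeline's logic and arithmetic on recoverable inputs, not the
end-to-end extraction quality achievable on a real literature corpus,
which is bounded by the chosen NER backend.

## Numerical and design choices

- Logarithms are natural internally; NPMI is a ratio of logarithms and
  provably base-invariant (asserted in tests against base 2), PMI is
  reported in the configured base.
- NPMI for a pair present in every document (−log p(x,y) = 0) is defined
  as 1 by limit and logged; Cramér's V is defined as 0 when a margin of
  the 2×2 table is degenerate (χ² undefined).
- Edge display names join the two endpoint names with an em dash in
  alphabetical order; an ASCII fallback (`--`) is a flag. Endpoints are
  always stored as a pair and never re-parsed from the display name, so
  concept names containing the separator are safe.
- Problem sizes: the test-suite oracle checks enumerate all simple
  minimal paths on 100 random graphs of up to 30 nodes and recount
  co-occurrences by brute force on corpora of up to 50 documents —
  scales at which exhaustive oracles are exact and fast.
- All orderings (lexicon terms, mentions, edges, postings, rankings,
  candidate ties) are explicitly sorted, so every stage is byte-stable
  across re-runs.

## Limitations

- The default dictionary matcher has perfect precision on its own
  lexicon but no recall beyond it; real-corpus recall requires plugging
  in a trained NER model.
- Utility terms default to the three shipped examples ("high",
  "increased", "induces"); the list is intentionally minimal and
  user-extensible, as no canonical inventory exists.
- Path enumeration is exhaustive at the minimal hop length; on very
  dense graphs with a large number of equal-length paths this can grow
  combinatorially before truncation to the top 10.
- The inverted index and network live in memory and serialize to flat
  files; no incremental update or database persistence is provided.
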