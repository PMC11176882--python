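# litgraph

Graph-query search over a co-occurrence network of biomedical
literature.

`litgraph` is for researchers who want to interrogate a corpus of
publication abstracts (the CORD-19 `metadata.csv` dialect) with *small
graph queries* instead of keyword lists: "which publications connect
SARS-CoV-2 to ACE2, and ACE2 to vascular permeability through
angiotensin II?". It builds an ontology-annotated co-occurrence network
from the corpus, matches the query against it inexactly, and ranks
publications by how many of the query's relationships they explain.

## The method

**Network construction.** Abstracts and titles are scanned for terms of
a UMLS/CIDO-style lexicon (deterministic dictionary matcher by default;
any NER backend can be plugged in). Mentions whose normalized
Levenshtein similarity to the linked concept falls below 0.7 are
discarded; *utility* terms (level modifiers such as "high", connectors
such as "induces") are always admitted. Nodes carry a document
frequency; an edge joins two concepts co-mentioned in ≥ 1 document and
carries, for joint document probability *p(x,y)* and marginals *p(x)*,
*p(y)*:

- PMI = log *p(x,y)* / (*p(x)* *p(y)*)
- NPMI = PMI / (−log *p(x,y)*) ∈ [−1, 1]
- Cramér's V = √(χ²/N) on the 2×2 presence/absence table

Edges with NPMI ≤ 0 (no positive association) are pruned, and the graph
is checked for being a single connected component.

**Search.** A graph query *Q* is a connected graph over network
concepts; its edges `rels(Q)` need not exist in the network. Each
missing edge is *expanded* into all minimal-hop simple paths between its
endpoints; candidates are ranked by average NPMI and the top 10
retained; one path per expansion is selected (top rank by default, user
override supported). Publications are fetched from an inverted index
(edge → sorted posting list of documents co-mentioning its endpoints)
and scored by the number of explained relationships,

score(P, Q) = Σ_{r ∈ rels(Q)} |{edges of path(r) mentioned in P}| / |path(r)|,

then ranked by (score, NPMI sum of mentioned edges, publication date,
record id); ranking by citation count is optional.

## Worked example

`make-fixtures` writes a synthetic corpus reproducing a 6-concept,
5-relationship query whose expansions and scores are known by
construction:

```
litgraph make-fixtures --out fix
litgraph clean --input fix/metadata.csv --out cleaned.csv
litgraph annotate --corpus cleaned.csv --lexicon fix/lexicon.tsv --out mentions.tsv
litgraph build-network --corpus cleaned.csv --mentions mentions.tsv \
    --lexicon fix/lexicon.tsv --out net
litgraph index --network net
litgraph search --network net --query fix/query.json \
    --corpus cleaned.csv --out results.tsv
```

which logs, stage by stage:

```
clean: 284 rows in, 284 records kept -> cleaned.csv
annotate: 338 mentions from 284 records -> mentions.tsv
build-network: 13 entities, 14 relationships (corpus N=284); 1 component(s) -> net
index: 14 posting lists -> net/index.jsonl
search: 26 publications ranked -> results.tsv
```

and ranks:

```
rank  record_id  score     explained  addends_json
1     pub0001    4.500000  4.5/5      {"ACE2—AngII": 1.0, "ACE2—SARS-CoV-2": 1.0,
                                       "AngII—Hypertension": 1.0,
                                       "AngII—Vascular Permeability": 0.5,
                                       "Hypertension—Inflammation": 1.0}
2     pub0002    3.666667  3.66667/5  {... "ACE2—SARS-CoV-2": 0.666667,
                                       "AngII—Vascular Permeability": 0.0 ...}
```

Publication 1 explains all of four relationships but only one of the two
edges of the selected AngII → (1,0)' → Vascular Permeability path, hence
the 0.5 addend and total 4.5. Publication 2 never co-occurs with that
path (addend 0) and explains 2 of the 3 edges of the selected
SARS-CoV-2 ↔ ACE2 path (addend 2/3), totalling 11/3 ≈ 3.667. The same
results are available through the Python API (`litgraph.search`,
`litgraph.worked_example_fixture`).

## Layout

- `litgraph.lexicon` — ontology vocabulary + utility terms (TSV / text)
- `litgraph.corpus` — cleaning, deduplication, mention extraction, curation
- `litgraph.network` — link mining, PMI/NPMI/Cramér's V, pruning, inverted index
- `litgraph.query` — validation, path expansion, scoring, ranking
- `litgraph.fixtures` — synthetic corpus generators and the worked example
- `litgraph.cli` — the staged command-line pipeline

See `docs/methods.md` for the model, parameter defaults, numerical
choices and limitations.
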