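"""End-to-end orchestration: metadata table -> network + inverted index.

Thin glue over the corpus and network modules, shared by the CLI stages,
the fixtures, and the tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import corpus as corpus_mod
from . import network as network_mod
from .corpus import EntityTable, MentionRecord, PublicationRecord
from .lexicon import Lexicon
from .network import CoOccurrenceNetwork, InvertedIndex

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    records: list[PublicationRecord]
    mentions: list[MentionRecord]
    entity_table: EntityTable
    network: CoOccurrenceNetwork
    index: InvertedIndex

    @property
    def metadata(self) -> dict[str, PublicationRecord]:
        return {r.record_id: r for r in self.records}


def run_pipeline(
    raw_metadata: pd.DataFrame,
    lexicon: Lexicon,
    threshold: float = 0.7,
    min_year: int = corpus_mod.DEFAULT_MIN_YEAR,
    exclusion_terms: Sequence[str] = corpus_mod.DEFAULT_EXCLUSION_TERMS,
    min_npmi: float = 0.0,
    log_base: float = math.e,
    separator: str = network_mod.DEFAULT_SEPARATOR,
) -> PipelineResult:
    """clean -> annotate -> curate -> build network -> invert, in memory."""
    records = corpus_mod.clean_and_dedupe(
        raw_metadata, min_year=min_year, exclusion_terms=exclusion_terms
    )
    mentions = corpus_mod.extract_corpus_mentions(records, lexicon)
    entity_table = corpus_mod.curate_entities(mentions, threshold=threshold)
    net = network_mod.build_network(
        entity_table,
        corpus_size=len(records),
        min_npmi=min_npmi,
        log_base=log_base,
        separator=separator,
    )
    index = network_mod.build_inverted_index(
        net.edges.values(), entity_table.doc_entities, separator=separator
    )
    return PipelineResult(
        records=records,
        mentions=mentions,
        entity_table=entity_table,
        network=net,
        index=index,
    )
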