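"""End-to-end search strategies.

Query construction for the two search modes (prior-art queries built from a
patent's title/abstract/claims; ad-hoc keyword queries), IPC query
augmentation, and co-citation re-ranking: patents are ranked by how often
they are cited within the collection and this citation signal is linearly
combined with the retrieval score, the premise being that frequently cited
patents are more likely to be relevant prior art regardless of the query.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from ._ipc import normalize_ipc_code
from .corpus import PatentCorpus, PatentDocument, Scope, extract_field_text
from .index import IndexConfig, InvertedIndex, process_text
from .ranking import (
    OutOfVocabularyError,
    Query,
    RankedResultList,
    RankingParams,
    retrieve,
)

__all__ = [
    "CitationTable",
    "RerankConfig",
    "build_prior_art_query",
    "build_adhoc_query",
    "normalize_ipc_code",
    "augment_query_with_ipc",
    "compute_citation_counts",
    "rerank_with_citations",
    "run_search",
]


@dataclass
class CitationTable:
    """In-collection citation counts: doc_id -> number of citing patents."""

    counts: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, doc_id: str) -> int:
        return self.counts.get(doc_id, 0)


@dataclass(frozen=True)
class RerankConfig:
    """Linear-combination re-ranking configuration.

    alpha weights the citation component; log1p damping tames the heavy tail
    of citation counts before min-max scaling.
    """

    alpha: float = 0.2
    damping: str = "log1p"  # log1p | none

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.damping not in ("log1p", "none"):
            raise ValueError(f"unknown damping: {self.damping!r}")


def build_prior_art_query(
    doc: PatentDocument, index_config: IndexConfig, query_id: str | None = None
) -> Query:
    """Query for a prior-art search: the patent's TAC text as a term bag.

    The description never enters the query, mirroring the topic definition of
    the prior-art benchmark (title, abstract and claims of a filed patent).
    """
    tokens = process_text(extract_field_text(doc, Scope.TAC), index_config)
    if not tokens:
        raise ValueError(f"patent {doc.patent_id} has empty TAC text")
    return Query(terms=dict(Counter(tokens)), query_id=query_id or doc.patent_id)


def build_adhoc_query(
    keywords: str, index_config: IndexConfig | None = None, query_id: str = "Q0"
) -> Query:
    """Query from short keyword text (technical-survey / known-item mode)."""
    index_config = index_config or IndexConfig()
    tokens = process_text(keywords, index_config)
    if not tokens:
        raise ValueError("query is empty after processing")
    return Query(terms=dict(Counter(tokens)), query_id=query_id)


def augment_query_with_ipc(query: Query, codes: list[str]) -> Query:
    """Add IPC pseudo-tokens (qtf 1 each, deduplicated) to a query."""
    ipc_tokens: set[str] = set()
    for code in codes:
        ipc_tokens |= normalize_ipc_code(code)
    terms = dict(query.terms)
    for tok in sorted(ipc_tokens):
        terms.setdefault(tok, 1)
    return Query(terms=terms, query_id=query.query_id)


def compute_citation_counts(corpus: PatentCorpus) -> CitationTable:
    """Count, per corpus patent, the distinct corpus patents citing it.

    Self-citations and citations from/to ids outside the corpus are ignored.
    """
    counts = {doc.patent_id: 0 for doc in corpus}
    for doc in corpus:
        for cited in set(doc.cited_ids):
            if cited == doc.patent_id:
                continue
            if cited in counts:
                counts[cited] += 1
    return CitationTable(counts=counts)


def _minmax(values: list[float]) -> list[float]:
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def rerank_with_citations(
    ranked: RankedResultList, table: CitationTable, config: RerankConfig | None = None
) -> RankedResultList:
    """Linearly combine retrieval scores with citation counts and re-sort.

    Both components are min-max normalized within the retrieved list (a
    component with no spread normalizes to all zeros); the final score is
    (1-alpha)*s_ir + alpha*s_cit.  The output is a permutation of the input:
    no document is added or removed.
    """
    config = config or RerankConfig()
    if not ranked.items:
        raise ValueError("cannot rerank an empty result list")
    ir = _minmax([score for _, score in ranked.items])
    raw_cit = [float(table[doc_id]) for doc_id, _ in ranked.items]
    if config.damping == "log1p":
        raw_cit = [math.log1p(c) for c in raw_cit]
    cit = _minmax(raw_cit)
    combined = [
        (doc_id, (1.0 - config.alpha) * s_ir + config.alpha * s_cit)
        for (doc_id, _), s_ir, s_cit in zip(ranked.items, ir, cit)
    ]
    combined.sort(key=lambda item: (-item[1], item[0]))
    return RankedResultList(query_id=ranked.query_id, items=combined)


def run_search(
    index: InvertedIndex,
    corpus: PatentCorpus,
    topics,
    params: RankingParams | None = None,
    *,
    ipc_boost: bool = False,
    rerank: RerankConfig | None = None,
    citation_table: CitationTable | None = None,
    exclude_self: bool = True,
) -> dict[str, RankedResultList]:
    """Run a topic set end to end; returns query_id -> ranked results.

    Per topic: build the query (prior-art topics use the source patent's TAC
    text, ad-hoc topics their keyword text), optionally augment with the
    topic's IPC codes, retrieve, optionally rerank by co-citations, and for
    prior-art topics optionally drop the source patent from its own results.
    A topic whose every term is out of vocabulary yields an empty result
    list rather than aborting the run.
    """
    params = params or RankingParams()
    if rerank is not None and citation_table is None:
        citation_table = compute_citation_counts(corpus)
    results: dict[str, RankedResultList] = {}
    for topic in topics:
        if topic.kind == "PA":
            source = corpus.get(topic.source_patent_id)
            if source is None:
                raise ValueError(
                    f"topic {topic.topic_id} references unknown patent "
                    f"{topic.source_patent_id}"
                )
            query = build_prior_art_query(source, index.config, query_id=topic.topic_id)
        else:
            query = build_adhoc_query(
                topic.query_text, index.config, query_id=topic.topic_id
            )
        if ipc_boost and topic.ipc_codes:
            query = augment_query_with_ipc(query, topic.ipc_codes)
        try:
            ranked = retrieve(index, query, params)
        except OutOfVocabularyError:
            ranked = RankedResultList(query_id=topic.topic_id, items=[])
        if topic.kind == "PA" and exclude_self and ranked.items:
            ranked = RankedResultList(
                query_id=ranked.query_id,
                items=[
                    (d, s) for d, s in ranked.items if d != topic.source_patent_id
                ],
            )
        if rerank is not None and ranked.items:
            ranked = rerank_with_citations(ranked, citation_table, rerank)
        results[topic.topic_id] = ranked
    return results
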