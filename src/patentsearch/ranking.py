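"""Okapi BM25 and PL2 divergence-from-randomness term weighting and top-k
retrieval over the inverted index.

BM25 scores a term as idf * ((k1+1)*tf) / (k1*((1-b) + b*dl/avdl) + tf) with
idf = ln((N - df + 0.5)/(df + 0.5)) floored at zero, so a term occurring in
more than half the collection contributes nothing rather than a negative
amount.

PL2 is the divergence-from-randomness model with a Poisson randomness model,
Laplace after-effect and length normalization 2: the term frequency is first
normalized to tfn = tf * log2(1 + c*avdl/dl), then scored as

    (1/(tfn+1)) * ( tfn*log2(tfn/lambda)
                    + (lambda + 1/(12*tfn) - tfn)*log2(e)
                    + 0.5*log2(2*pi*tfn) )

with lambda = cf/N the Poisson rate of the term in the collection.  The PL2
value is kept exactly as the formula computes it — no floor or clamp is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .index import CollectionStats, InvertedIndex

__all__ = [
    "RankingParams",
    "Query",
    "RankedResultList",
    "EmptyQueryError",
    "OutOfVocabularyError",
    "bm25_term_weight",
    "pl2_term_weight",
    "score_document_bruteforce",
    "retrieve",
]

_LOG2E = math.log2(math.e)


class EmptyQueryError(ValueError):
    """The query contained no terms at all after processing."""


class OutOfVocabularyError(ValueError):
    """Every query term is absent from the index vocabulary."""


@dataclass(frozen=True)
class RankingParams:
    model: str = "BM25"  # BM25 | PL2
    k1: float = 1.2
    b: float = 0.75
    c: float = 1.0
    k: int = 1000

    def __post_init__(self) -> None:
        if self.model not in ("BM25", "PL2"):
            raise ValueError(f"unknown model: {self.model!r}")
        if self.k1 <= 0 or self.c <= 0:
            raise ValueError("k1 and c must be positive")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("b must lie in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class Query:
    """A processed query: a bag of index-side tokens with frequencies."""

    terms: dict[str, int] = field(default_factory=dict)
    query_id: str = "Q0"

    def __post_init__(self) -> None:
        if any(qtf < 1 for qtf in self.terms.values()):
            raise ValueError("query term frequencies must be >= 1")


@dataclass
class RankedResultList:
    """Ordered (doc_id, score) pairs, score descending, ties by doc_id."""

    query_id: str
    items: list[tuple[str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def doc_ids(self) -> list[str]:
        return [d for d, _ in self.items]


def bm25_term_weight(
    tf: int, df: int, dl: float, stats: CollectionStats, params: RankingParams
) -> float:
    """BM25 contribution of one term occurrence profile to one document."""
    if tf < 1:
        raise ValueError("tf must be >= 1")
    if not 1 <= df <= stats.N:
        raise ValueError(f"df={df} out of range for N={stats.N}")
    if stats.avdl <= 0:
        raise ValueError("avdl must be positive")
    idf = math.log((stats.N - df + 0.5) / (df + 0.5))
    if idf <= 0.0:
        return 0.0
    denom = params.k1 * ((1.0 - params.b) + params.b * dl / stats.avdl) + tf
    return idf * ((params.k1 + 1.0) * tf) / denom


def pl2_term_weight(
    tf: int, cf: int, dl: float, stats: CollectionStats, params: RankingParams
) -> float:
    """PL2 contribution, returned exactly as the formula computes it."""
    if tf < 1 or cf < 1:
        raise ValueError("tf and cf must be >= 1")
    if dl <= 0:
        raise ValueError("dl must be positive")
    tfn = tf * math.log2(1.0 + params.c * stats.avdl / dl)
    lam = cf / stats.N
    return (1.0 / (tfn + 1.0)) * (
        tfn * math.log2(tfn / lam)
        + (lam + 1.0 / (12.0 * tfn) - tfn) * _LOG2E
        + 0.5 * math.log2(2.0 * math.pi * tfn)
    )


def _term_weight(
    tf: int, term: str, dl: float, index: InvertedIndex, params: RankingParams
) -> float:
    stats = index.stats
    if params.model == "BM25":
        return bm25_term_weight(tf, stats.df[term], dl, stats, params)
    return pl2_term_weight(tf, stats.cf[term], dl, stats, params)


def score_document_bruteforce(
    query: Query, doc_id: str, index: InvertedIndex, params: RankingParams
) -> float:
    """Score one document by direct per-term lookup (testing oracle).

    Sums qtf * term_weight over the query terms using a per-document tf
    lookup rather than the posting-traversal accumulation of
    :func:`retrieve`.
    """
    if doc_id not in index.doc_lengths:
        raise KeyError(f"unknown document: {doc_id}")
    dl = index.doc_lengths[doc_id]
    score = 0.0
    for term, qtf in query.terms.items():
        plist = index.postings.get(term)
        if plist is None:
            continue
        tf = dict(plist).get(doc_id)
        if tf is None:
            continue
        score += qtf * _term_weight(tf, term, dl, index, params)
    return score


def retrieve(
    index: InvertedIndex, query: Query, params: RankingParams | None = None
) -> RankedResultList:
    """Term-at-a-time retrieval: top-k documents by (score desc, doc_id asc).

    Documents whose total score is <= 0 are omitted.  Raises
    :class:`EmptyQueryError` for a query with no terms and
    :class:`OutOfVocabularyError` when no query term occurs in the index.
    """
    params = params or RankingParams()
    if not query.terms:
        raise EmptyQueryError("query is empty after processing")
    matched = [t for t in query.terms if t in index.postings]
    if not matched:
        raise OutOfVocabularyError(
            "all query terms are out of the index vocabulary"
        )
    scores: dict[str, float] = {}
    doc_lengths = index.doc_lengths
    for term in matched:
        qtf = query.terms[term]
        for doc_id, tf in index.postings[term]:
            w = qtf * _term_weight(tf, term, doc_lengths[doc_id], index, params)
            scores[doc_id] = scores.get(doc_id, 0.0) + w
    items = [(d, s) for d, s in scores.items() if s > 0.0]
    items.sort(key=lambda item: (-item[1], item[0]))
    return RankedResultList(query_id=query.query_id, items=items[: params.k])
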