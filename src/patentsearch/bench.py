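"""Benchmark construction and TREC-style I/O.

Three benchmark kinds:

* prior art (PA): the topic is a patent; the relevant documents are the
  patents it cites, restricted to those present in the collection (cited
  documents absent from the collection cannot be retrieved, so they are
  excluded from the judgments).
* technical survey (TS): short keyword topics, possibly with IPC codes.
* known-item (KI): ten words sampled from a patent's title/abstract/claims;
  the single relevant document is the patent the words came from.

Topics are stored in a small XML dialect; qrels and run files use the plain
TREC text formats (``qid 0 docid rel`` / ``qid Q0 docid rank score tag``).
Run files store a 0-based rank column; the reader ignores it and re-sorts by
(qid, score desc, docid asc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from ._stopwords import DEFAULT_STOPWORDS
from .corpus import PatentCorpus, Scope, extract_field_text
from .index import tokenize
from .ranking import RankedResultList

__all__ = [
    "Topic",
    "Qrels",
    "build_prior_art_benchmark",
    "build_known_item_benchmark",
    "read_topics",
    "write_topics",
    "read_qrels",
    "write_qrels",
    "read_run",
    "write_run",
]

Qrels = dict[str, set[str]]


@dataclass
class Topic:
    """One benchmark topic."""

    topic_id: str
    kind: str  # PA | TS | KI
    query_text: str = ""
    source_patent_id: str = ""
    ipc_codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("PA", "TS", "KI"):
            raise ValueError(f"unknown topic kind: {self.kind!r}")


def build_prior_art_benchmark(
    corpus: PatentCorpus, n_topics: int, seed: int
) -> tuple[list[Topic], Qrels]:
    """Sample prior-art topics with citation-derived relevance judgments.

    Candidate topics are patents with at least one in-corpus cited patent
    (other than themselves).  ``n_topics`` candidates are sampled uniformly
    without replacement under ``seed``; qrels are the in-corpus cited sets,
    never containing the source patent.  If fewer candidates exist, all are
    used and a warning is issued.
    """
    candidates = []
    for doc in corpus:
        cited_in = {
            c for c in doc.cited_ids if c in corpus and c != doc.patent_id
        }
        if cited_in:
            candidates.append((doc.patent_id, cited_in))
    if not candidates:
        raise ValueError("no patent has in-corpus citations; cannot build PA benchmark")
    rng = np.random.default_rng(seed)
    if len(candidates) < n_topics:
        warnings.warn(
            f"only {len(candidates)} PA candidates available, requested {n_topics}"
        )
        chosen = list(range(len(candidates)))
    else:
        chosen = sorted(rng.choice(len(candidates), size=n_topics, replace=False))
    topics: list[Topic] = []
    qrels: Qrels = {}
    for rank, idx in enumerate(chosen, start=1):
        pid, relevant = candidates[idx]
        topic_id = f"PA-{rank}"
        topics.append(
            Topic(
                topic_id=topic_id,
                kind="PA",
                source_patent_id=pid,
                ipc_codes=list(corpus[pid].ipc_codes),
            )
        )
        qrels[topic_id] = relevant
    return topics, qrels


def eligible_known_item_words(doc, stopwords=DEFAULT_STOPWORDS) -> list[str]:
    """Distinct lowercased TAC tokens, stopwords removed, length >= 2."""
    tokens = tokenize(extract_field_text(doc, Scope.TAC))
    return sorted({t for t in tokens if len(t) >= 2 and t not in stopwords})


def build_known_item_benchmark(
    corpus: PatentCorpus,
    n_topics: int,
    words_per_topic: int = 10,
    seed: int = 0,
    stopwords=DEFAULT_STOPWORDS,
) -> tuple[list[Topic], Qrels]:
    """Sample known-item topics: ``words_per_topic`` distinct words from a
    patent's TAC text; the patent itself is the single relevant document.

    Patents with fewer eligible words than ``words_per_topic`` are skipped.
    """
    eligible = []
    for doc in corpus:
        words = eligible_known_item_words(doc, stopwords)
        if len(words) >= words_per_topic:
            eligible.append((doc.patent_id, words))
    if not eligible:
        raise ValueError("no patent has enough eligible words for known-item topics")
    rng = np.random.default_rng(seed)
    if len(eligible) < n_topics:
        warnings.warn(
            f"only {len(eligible)} known-item candidates available, requested {n_topics}"
        )
        chosen = list(range(len(eligible)))
    else:
        chosen = sorted(rng.choice(len(eligible), size=n_topics, replace=False))
    topics: list[Topic] = []
    qrels: Qrels = {}
    for rank, idx in enumerate(chosen, start=1):
        pid, words = eligible[idx]
        sampled = rng.choice(len(words), size=words_per_topic, replace=False)
        query = " ".join(words[i] for i in sampled)
        topic_id = f"KI-{rank}"
        topics.append(
            Topic(
                topic_id=topic_id,
                kind="KI",
                query_text=query,
                source_patent_id=pid,
                ipc_codes=list(corpus[pid].ipc_codes),
            )
        )
        qrels[topic_id] = {pid}
    return topics, qrels


# ---------------------------------------------------------------------------
# Topics XML


def write_topics(topics: list[Topic], path: str | Path) -> None:
    root = etree.Element("topics")
    for topic in topics:
        el = etree.SubElement(root, "topic")
        el.set("id", topic.topic_id)
        el.set("kind", topic.kind)
        if topic.kind == "PA":
            etree.SubElement(el, "source").text = topic.source_patent_id
        else:
            etree.SubElement(el, "query").text = topic.query_text
            if topic.source_patent_id:
                etree.SubElement(el, "source").text = topic.source_patent_id
        for code in topic.ipc_codes:
            etree.SubElement(el, "ipc").text = code
    etree.ElementTree(root).write(
        str(path), encoding="utf-8", xml_declaration=True, pretty_print=True
    )


def read_topics(path: str | Path) -> list[Topic]:
    tree = etree.parse(str(path))
    topics: list[Topic] = []
    seen: set[str] = set()
    for el in tree.getroot().iter("topic"):
        topic_id = el.get("id", "")
        if topic_id in seen:
            raise ValueError(f"duplicate topic id: {topic_id}")
        seen.add(topic_id)
        topics.append(
            Topic(
                topic_id=topic_id,
                kind=el.get("kind", ""),
                query_text=el.findtext("query", default=""),
                source_patent_id=el.findtext("source", default=""),
                ipc_codes=[c.text or "" for c in el.iter("ipc")],
            )
        )
    return topics


# ---------------------------------------------------------------------------
# TREC qrels and run files


def write_qrels(qrels: Qrels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for qid in qrels:
            for doc_id in sorted(qrels[qid]):
                fh.write(f"{qid} 0 {doc_id} 1\n")


def read_qrels(path: str | Path) -> Qrels:
    qrels: Qrels = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            qid, _, doc_id, rel = parts
            try:
                rel_val = int(rel)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric relevance {rel!r}") from exc
            if rel_val > 0:
                qrels.setdefault(qid, set()).add(doc_id)
            else:
                qrels.setdefault(qid, set())
    return qrels


def write_run(
    runs: dict[str, RankedResultList], path: str | Path, tag: str = "patentsearch"
) -> None:
    """Write TREC run lines ``qid Q0 docid rank score tag`` (0-based ranks)."""
    with open(path, "w", encoding="utf-8") as fh:
        for qid in runs:
            for rank, (doc_id, score) in enumerate(runs[qid].items):
                fh.write(f"{qid} Q0 {doc_id} {rank} {score:.6f} {tag}\n")


def read_run(path: str | Path) -> dict[str, RankedResultList]:
    """Read a TREC run; the stored rank column is ignored and each topic's
    list is re-sorted by (score desc, docid asc)."""
    raw: dict[str, list[tuple[str, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields")
            qid, _, doc_id, _rank, score, _tag = parts
            try:
                score_val = float(score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score {score!r}") from exc
            raw.setdefault(qid, []).append((doc_id, score_val))
    runs: dict[str, RankedResultList] = {}
    for qid, items in raw.items():
        items.sort(key=lambda item: (-item[1], item[0]))
        runs[qid] = RankedResultList(query_id=qid, items=items)
    return runs
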