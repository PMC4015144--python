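"""Tokenization, Porter stemming, stopword removal and inverted indexing.

An index is built under a field-selection config: with or without the
description field, and with or without normalized-concept metadata.  The
index holds a single bag-of-tokens field per document in which dictionary
concepts appear as ``CONCEPT_<source>_<id>`` pseudo-tokens and IPC codes as
``IPC_<code>`` pseudo-tokens; identifiers are never stemmed, text tokens are
stopword-filtered then Porter-stemmed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ._ipc import normalize_ipc_code
from ._porter import porter_stem
from ._stopwords import DEFAULT_STOPWORDS
from .corpus import PatentCorpus, Scope, extract_field_text

__all__ = [
    "IndexConfig",
    "CollectionStats",
    "InvertedIndex",
    "tokenize",
    "porter_stem",
    "process_text",
    "build_index",
    "term_stats",
]

CONCEPT_PREFIX = "CONCEPT_"

# one or more Unicode letters/digits (underscore excluded)
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)

FORMAT_VERSION = 1


def tokenize(text: str) -> list[str]:
    """Lowercase and split on any character that is not a letter or digit."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class IndexConfig:
    """Field-selection and processing configuration for one index."""

    include_description: bool = False
    metadata_mode: str = "NONE"  # NONE | TAC | TACD
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    min_token_length: int = 1

    def __post_init__(self) -> None:
        if self.metadata_mode not in ("NONE", "TAC", "TACD"):
            raise ValueError(f"invalid metadata_mode: {self.metadata_mode!r}")
        if self.min_token_length < 1:
            raise ValueError("min_token_length must be >= 1")


@dataclass
class CollectionStats:
    """Collection statistics needed by the term-weighting models.

    N: indexed documents; avdl: mean document length (tokens);
    df: per-term number of documents containing the term;
    cf: per-term total occurrence count in the collection.
    """

    N: int
    avdl: float
    df: dict[str, int] = field(default_factory=dict)
    cf: dict[str, int] = field(default_factory=dict)


@dataclass
class InvertedIndex:
    """Postings, document lengths and collection statistics.

    ``postings`` maps term -> list of (doc_id, tf), sorted by doc_id.
    """

    postings: dict[str, list[tuple[str, int]]]
    doc_lengths: dict[str, int]
    stats: CollectionStats
    config: IndexConfig

    def __contains__(self, term: str) -> bool:
        return term in self.postings

    # -- flat-file persistence (versioned, plain text) ------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = {
            "format_version": FORMAT_VERSION,
            "include_description": self.config.include_description,
            "metadata_mode": self.config.metadata_mode,
            "min_token_length": self.config.min_token_length,
            "stopwords": sorted(self.config.stopwords),
            "N": self.stats.N,
            "avdl": self.stats.avdl,
        }
        (directory / "config.json").write_text(
            json.dumps(cfg, indent=1, sort_keys=True), encoding="utf-8"
        )
        with open(directory / "docs.tsv", "w", encoding="utf-8") as fh:
            for doc_id, dl in self.doc_lengths.items():
                fh.write(f"{doc_id}\t{dl}\n")
        with open(directory / "postings.tsv", "w", encoding="utf-8") as fh:
            for term in sorted(self.postings):
                plist = ",".join(f"{d}:{tf}" for d, tf in self.postings[term])
                fh.write(f"{term}\t{plist}\n")

    @classmethod
    def load(cls, directory: str | Path) -> "InvertedIndex":
        directory = Path(directory)
        cfg = json.loads((directory / "config.json").read_text(encoding="utf-8"))
        if cfg.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported index format: {cfg.get('format_version')}")
        config = IndexConfig(
            include_description=cfg["include_description"],
            metadata_mode=cfg["metadata_mode"],
            stopwords=frozenset(cfg["stopwords"]),
            min_token_length=cfg["min_token_length"],
        )
        doc_lengths: dict[str, int] = {}
        for line in (directory / "docs.tsv").read_text(encoding="utf-8").splitlines():
            doc_id, dl = line.split("\t")
            doc_lengths[doc_id] = int(dl)
        postings: dict[str, list[tuple[str, int]]] = {}
        df: dict[str, int] = {}
        cf: dict[str, int] = {}
        for line in (directory / "postings.tsv").read_text(encoding="utf-8").splitlines():
            term, plist = line.split("\t")
            entries = []
            for item in plist.split(","):
                d, tf = item.rsplit(":", 1)
                entries.append((d, int(tf)))
            postings[term] = entries
            df[term] = len(entries)
            cf[term] = sum(tf for _, tf in entries)
        stats = CollectionStats(N=cfg["N"], avdl=cfg["avdl"], df=df, cf=cf)
        return cls(postings=postings, doc_lengths=doc_lengths, stats=stats, config=config)


def process_text(text: str, config: IndexConfig) -> list[str]:
    """Tokenize, drop stopwords and short tokens, then Porter-stem.

    Stopword removal happens before stemming so that the list operates on
    surface forms.  Used identically on the index side and the query side.
    """
    out = []
    min_len = config.min_token_length
    stop = config.stopwords
    for tok in tokenize(text):
        if len(tok) < min_len or tok in stop:
            continue
        out.append(porter_stem(tok))
    return out


def document_tokens(doc, config: IndexConfig) -> list[str]:
    """All index tokens of one document under ``config``.

    Text tokens from the selected scope, concept pseudo-tokens when the
    metadata mode matches the document's stored normalization scope, and IPC
    pseudo-tokens.  Concept and IPC tokens are identifiers and are not
    stemmed or stopword-filtered.
    """
    scope = Scope.TACD if config.include_description else Scope.TAC
    tokens = process_text(extract_field_text(doc, scope), config)
    if config.metadata_mode != "NONE":
        if doc.metadata_scope is not None and doc.metadata_scope.value == config.metadata_mode:
            for source, concept_id in doc.metadata:
                tokens.append(f"{CONCEPT_PREFIX}{source}_{concept_id}")
    for code in doc.ipc_codes:
        tokens.extend(sorted(normalize_ipc_code(code)))
    return tokens


def build_index(corpus: PatentCorpus, config: IndexConfig | None = None) -> InvertedIndex:
    """Build an inverted index over ``corpus`` under ``config``.

    Raises ValueError when a metadata mode is requested but no document in
    the corpus carries metadata of that scope.
    """
    config = config or IndexConfig()
    if len(corpus) == 0:
        raise ValueError("cannot index an empty corpus")
    if config.metadata_mode != "NONE":
        if not any(
            doc.metadata_scope is not None
            and doc.metadata_scope.value == config.metadata_mode
            for doc in corpus
        ):
            raise ValueError(
                f"metadata_mode={config.metadata_mode} requested but the corpus "
                f"carries no metadata of that scope (run normalization first)"
            )
    postings_map: dict[str, dict[str, int]] = {}
    doc_lengths: dict[str, int] = {}
    for doc in corpus:
        tokens = document_tokens(doc, config)
        doc_lengths[doc.patent_id] = len(tokens)
        counts: dict[str, int] = {}
        for tok in tokens:
            counts[tok] = counts.get(tok, 0) + 1
        for tok, tf in counts.items():
            postings_map.setdefault(tok, {})[doc.patent_id] = tf
    postings = {
        term: sorted(doc_tfs.items()) for term, doc_tfs in postings_map.items()
    }
    df = {term: len(plist) for term, plist in postings.items()}
    cf = {term: sum(tf for _, tf in plist) for term, plist in postings.items()}
    n = len(doc_lengths)
    avdl = sum(doc_lengths.values()) / n
    stats = CollectionStats(N=n, avdl=avdl, df=df, cf=cf)
    return InvertedIndex(postings=postings, doc_lengths=doc_lengths, stats=stats, config=config)


def term_stats(index: InvertedIndex, term: str) -> tuple[int, int]:
    """(df, cf) for ``term``; (0, 0) for terms absent from the index."""
    return index.stats.df.get(term, 0), index.stats.cf.get(term, 0)
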