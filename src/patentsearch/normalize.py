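"""Dictionary-driven normalization of patent text into concept metadata.

Terminology terms (synonym phrases from resources such as MeSH, GO or a
cell/tissue vocabulary) are matched against the tokenized TAC or TACD text of
each patent by greedy leftmost-longest, non-overlapping lookup on lowercased
token sequences — exact gazetteer matching, no stemming or fuzzy logic.
Matched concepts are stored on the document as (source, concept_id) metadata
tagged with the scope; the text fields themselves are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import PatentCorpus, PatentDocument, Scope, Terminology, extract_field_text
from .index import tokenize

__all__ = ["ConceptAnnotation", "annotate_text", "annotate_corpus"]


@dataclass(frozen=True)
class ConceptAnnotation:
    """One dictionary match: concept plus its token span (start incl., end excl.)."""

    source: str
    concept_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("annotation span must be non-empty")


def _compile(terminology: Terminology) -> tuple[dict[tuple[str, ...], tuple[str, str]], int]:
    table: dict[tuple[str, ...], tuple[str, str]] = {}
    max_len = 0
    for term, concept in terminology.entries.items():
        key = tuple(tokenize(term))
        if not key:
            continue
        table[key] = concept
        max_len = max(max_len, len(key))
    return table, max_len


def annotate_text(
    tokens: list[str], terminology: Terminology
) -> list[ConceptAnnotation]:
    """Greedy leftmost-longest non-overlapping matching over a token sequence.

    Terms are tokenized with the same tokenizer as the text; after a match,
    scanning resumes at the match end, so spans from one terminology never
    overlap.
    """
    table, max_len = _compile(terminology)
    annotations: list[ConceptAnnotation] = []
    if not table:
        return annotations
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 0, -1):
            concept = table.get(tuple(tokens[i : i + length]))
            if concept is not None:
                source, concept_id = concept
                annotations.append(
                    ConceptAnnotation(source=source, concept_id=concept_id, start=i, end=i + length)
                )
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return annotations


def annotate_document(
    doc: PatentDocument, terminologies: list[Terminology], scope: Scope | str
) -> PatentDocument:
    """Replace one document's metadata by its concept annotations (in place)."""
    scope = Scope(scope)
    tokens = tokenize(extract_field_text(doc, scope))
    metadata: list[tuple[str, str]] = []
    for terminology in terminologies:
        for ann in annotate_text(tokens, terminology):
            metadata.append((ann.source, ann.concept_id))
    doc.metadata = metadata
    doc.metadata_scope = scope
    return doc


def annotate_corpus(
    corpus: PatentCorpus, terminologies: list[Terminology], scope: Scope | str
) -> PatentCorpus:
    """Annotate every document; metadata is the union over all terminologies.

    Concepts are stored as a bag (duplicate matches kept) so that indexed
    metadata carries term frequencies.  Annotation is idempotent: re-running
    with the same inputs replaces the metadata with an identical bag.
    """
    for doc in corpus:
        annotate_document(doc, terminologies, scope)
    return corpus
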