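"""Patent data model and I/O.

Patents are exchanged in a small ad-hoc XML dialect (one ``<patent>`` element
per document under a ``<patents>`` root) and terminology dictionaries as
headerless TSV files with columns ``concept_id``, ``source``, ``term``.

Two field scopes recur throughout the engine: TAC (title + abstract + claims)
and TACD (TAC + description).  The description of a patent is typically an
order of magnitude longer than the other fields combined, which is why the
engine treats its inclusion as a tuning decision rather than a given.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

from lxml import etree

__all__ = [
    "Scope",
    "PatentDocument",
    "PatentCorpus",
    "Terminology",
    "read_patent_corpus",
    "write_patent_corpus",
    "read_terminology",
    "extract_field_text",
]


class Scope(str, Enum):
    """Field scope: title/abstract/claims, optionally plus description."""

    TAC = "TAC"
    TACD = "TACD"


def _normalize_id(raw: str) -> str:
    """Canonical patent id: uppercase, all whitespace removed."""
    return re.sub(r"\s+", "", raw).upper()


@dataclass
class PatentDocument:
    """One patent: text fields, IPC codes, outbound citations, metadata.

    ``metadata`` holds (source, concept_id) pairs produced by dictionary
    normalization, as a bag (duplicates kept so that indexed concepts carry
    term frequencies).  ``metadata_scope`` records which fields were
    normalized; it is ``None`` until normalization has run.
    """

    patent_id: str
    title: str = ""
    abstract: str = ""
    claims: str = ""
    description: str = ""
    ipc_codes: list[str] = field(default_factory=list)
    cited_ids: list[str] = field(default_factory=list)
    metadata: list[tuple[str, str]] = field(default_factory=list)
    metadata_scope: Scope | None = None

    def __post_init__(self) -> None:
        self.patent_id = _normalize_id(self.patent_id)
        if not self.patent_id:
            raise ValueError("patent_id must be non-empty")
        self.cited_ids = [_normalize_id(c) for c in self.cited_ids]


class PatentCorpus:
    """Ordered collection of :class:`PatentDocument` with id lookup."""

    def __init__(self, documents: Iterator[PatentDocument] | None = None):
        self._docs: dict[str, PatentDocument] = {}
        for doc in documents or ():
            self.add(doc)

    def add(self, doc: PatentDocument) -> None:
        if doc.patent_id in self._docs:
            raise ValueError(f"duplicate patent id: {doc.patent_id}")
        self._docs[doc.patent_id] = doc

    def __len__(self) -> int:
        return len(self._docs)

    def __iter__(self) -> Iterator[PatentDocument]:
        return iter(self._docs.values())

    def __contains__(self, patent_id: str) -> bool:
        return patent_id in self._docs

    def __getitem__(self, patent_id: str) -> PatentDocument:
        return self._docs[patent_id]

    def get(self, patent_id: str) -> PatentDocument | None:
        return self._docs.get(patent_id)

    @property
    def ids(self) -> list[str]:
        return list(self._docs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatentCorpus):
            return NotImplemented
        return list(self) == list(other)


@dataclass
class Terminology:
    """Synonym -> concept dictionary used for normalization.

    ``entries`` maps a lowercased, whitespace-normalized synonym term to a
    (source, concept_id) pair.  A term maps to exactly one concept within one
    terminology; a concept may have many synonym terms.
    """

    name: str
    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add_term(self, term: str, source: str, concept_id: str) -> None:
        key = _normalize_term(term)
        if not key:
            raise ValueError("terminology term must be non-empty")
        existing = self.entries.get(key)
        if existing is not None and existing != (source, concept_id):
            raise ValueError(
                f"term {key!r} already maps to {existing}, "
                f"cannot remap to {(source, concept_id)}"
            )
        self.entries[key] = (source, concept_id)

    @property
    def concept_ids(self) -> set[str]:
        return {cid for _, cid in self.entries.values()}

    def __len__(self) -> int:
        return len(self.entries)


def _normalize_term(term: str) -> str:
    return " ".join(term.lower().split())


def extract_field_text(doc: PatentDocument, scope: Scope | str) -> str:
    """Concatenate the scoped fields, newline-separated, in canonical order.

    TAC yields ``title\\nabstract\\nclaims``; TACD appends the description.
    Empty fields contribute an empty line (the separator structure is stable).
    """
    scope = Scope(scope)
    parts = [doc.title, doc.abstract, doc.claims]
    if scope is Scope.TACD:
        parts.append(doc.description)
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# XML dialect


def read_patent_corpus(path: str | Path) -> PatentCorpus:
    """Parse the patent XML dialect into a :class:`PatentCorpus`.

    Missing optional elements become empty values; patent ids are uppercased
    with whitespace stripped.  Malformed XML raises
    :class:`lxml.etree.XMLSyntaxError` (which names the offending line);
    duplicate ids raise :class:`ValueError`.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    corpus = PatentCorpus()
    for el in root.iter("patent"):
        pid = el.findtext("id", default="")
        meta_el = el.find("metadata")
        metadata: list[tuple[str, str]] = []
        metadata_scope: Scope | None = None
        if meta_el is not None:
            scope_attr = meta_el.get("scope")
            metadata_scope = Scope(scope_attr) if scope_attr else None
            for c in meta_el.iter("concept"):
                metadata.append((c.get("source", ""), c.text or ""))
        doc = PatentDocument(
            patent_id=pid,
            title=el.findtext("title", default=""),
            abstract=el.findtext("abstract", default=""),
            claims=el.findtext("claims", default=""),
            description=el.findtext("description", default=""),
            ipc_codes=[c.text or "" for c in el.iter("code")],
            cited_ids=[c.text or "" for c in el.iter("patcit")],
            metadata=metadata,
            metadata_scope=metadata_scope,
        )
        corpus.add(doc)
    return corpus


def write_patent_corpus(corpus: PatentCorpus, path: str | Path) -> None:
    """Serialize a corpus to the XML dialect (UTF-8, deterministic order)."""
    root = etree.Element("patents")
    for doc in corpus:
        el = etree.SubElement(root, "patent")
        etree.SubElement(el, "id").text = doc.patent_id
        etree.SubElement(el, "title").text = doc.title
        etree.SubElement(el, "abstract").text = doc.abstract
        etree.SubElement(el, "claims").text = doc.claims
        etree.SubElement(el, "description").text = doc.description
        if doc.ipc_codes:
            ipc = etree.SubElement(el, "ipc")
            for code in doc.ipc_codes:
                etree.SubElement(ipc, "code").text = code
        if doc.cited_ids:
            cits = etree.SubElement(el, "citations")
            for cid in doc.cited_ids:
                etree.SubElement(cits, "patcit").text = cid
        if doc.metadata:
            meta = etree.SubElement(el, "metadata")
            if doc.metadata_scope is not None:
                meta.set("scope", doc.metadata_scope.value)
            for source, concept_id in doc.metadata:
                c = etree.SubElement(meta, "concept")
                c.set("source", source)
                c.text = concept_id
    tree = etree.ElementTree(root)
    tree.write(str(path), encoding="utf-8", xml_declaration=True, pretty_print=True)


# ---------------------------------------------------------------------------
# Terminology TSV


def read_terminology(path: str | Path, name: str | None = None) -> Terminology:
    """Load a terminology from headerless TSV: concept_id<TAB>source<TAB>term.

    Terms are lowercased and whitespace-normalized on load.  A term row that
    remaps an already-seen term to a different concept raises ValueError; an
    empty file yields an empty terminology.
    """
    path = Path(path)
    term = Terminology(name=name or path.stem)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            concept_id, source, raw_term = parts
            term.add_term(raw_term, source, concept_id)
    return term
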