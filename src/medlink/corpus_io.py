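"""Data model and IO for documents, mentions, concept inventories, candidates.

The in-memory objects mirror the entity-linking task: a concept inventory is
the target space, an annotated corpus carries documents with character-offset
mentions, and a candidate list is the ranked shortlist a candidate generator
proposes for one mention.

Conventions (fixed, validated, and fail-loud):

* Document text is ``title + " " + abstract``.
* Offsets are 0-based, half-open, into that concatenated text.
* Every reader verifies the annotated surface against the text slice and
  rejects mismatches rather than repairing them.

Supported formats: PubTator-style corpora (``docid|t|title`` / ``docid|a|…``
lines followed by tab-separated annotation lines), a four-column inventory
TSV, and JSON-lines candidate files.  All UTF-8.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import (
    DanglingAnnotationError,
    DuplicateKeyError,
    InvalidEntryError,
    OffsetIntegrityError,
    OrderingError,
)
from .typescheme import TypeScheme


@dataclass(frozen=True)
class ConceptEntry:
    """One concept: identifier, names, and its fine semantic types."""

    cui: str
    preferred_name: str
    synonyms: tuple[str, ...]
    fine_types: frozenset[str]

    def __post_init__(self) -> None:
        if not self.cui:
            raise InvalidEntryError("concept with empty cui")
        if not self.fine_types:
            raise InvalidEntryError(f"concept {self.cui}: empty fine_types")

    @property
    def all_names(self) -> tuple[str, ...]:
        return (self.preferred_name, *self.synonyms)


@dataclass(frozen=True)
class ConceptInventory:
    """The predefined set of linkable concepts, keyed by CUI."""

    entries: Mapping[str, ConceptEntry]

    @classmethod
    def from_entries(cls, entries: Iterable[ConceptEntry]) -> "ConceptInventory":
        out: dict[str, ConceptEntry] = {}
        for e in entries:
            if e.cui in out:
                raise DuplicateKeyError(f"duplicate cui {e.cui!r}")
            out[e.cui] = e
        return cls(out)

    def __contains__(self, cui: str) -> bool:
        return cui in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, cui: str) -> ConceptEntry:
        return self.entries[cui]


@dataclass(frozen=True)
class Document:
    doc_id: str
    title: str
    abstract: str
    mesh_headers: tuple[str, ...] | None = None

    @property
    def text(self) -> str:
        """Title and abstract joined by a single space."""
        return f"{self.title} {self.abstract}"


@dataclass(frozen=True)
class Mention:
    """One annotated (or detected) span; offsets index ``Document.text``."""

    doc_id: str
    start: int
    end: int
    surface: str
    gold_cui: str | None = None
    gold_groups: frozenset[str] | None = None
    declared_type: str | None = None  # advisory type column from the source file

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise OffsetIntegrityError(
                f"{self.doc_id}: invalid offsets [{self.start}, {self.end})"
            )

    def check_against(self, doc: Document) -> None:
        """Verify the surface matches the text slice; raise if not."""
        if self.end > len(doc.text):
            raise OffsetIntegrityError(
                f"{self.doc_id}: span [{self.start}, {self.end}) exceeds text "
                f"length {len(doc.text)}"
            )
        piece = doc.text[self.start : self.end]
        if piece != self.surface:
            raise OffsetIntegrityError(
                f"{self.doc_id}: slice [{self.start}, {self.end}) reads "
                f"{piece!r}, annotation says {self.surface!r}"
            )

    @property
    def span_key(self) -> tuple[str, int, int]:
        return (self.doc_id, self.start, self.end)


@dataclass(frozen=True)
class CandidateList:
    """Ranked candidate concepts for one mention (scores non-increasing)."""

    mention: Mention
    candidates: tuple[tuple[str, float], ...]
    provenance: str = "dictionary"

    def __post_init__(self) -> None:
        cuis = [c for c, _ in self.candidates]
        if len(set(cuis)) != len(cuis):
            raise DuplicateKeyError(
                f"{self.mention.span_key}: duplicate candidate cui"
            )
        scores = [s for _, s in self.candidates]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise OrderingError(
                f"{self.mention.span_key}: candidate scores increase along the list"
            )

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def cuis(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.candidates)


@dataclass(frozen=True)
class AnnotatedCorpus:
    documents: tuple[Document, ...]
    mentions: tuple[Mention, ...] = field(default=())

    def __post_init__(self) -> None:
        by_id = {d.doc_id: d for d in self.documents}
        if len(by_id) != len(self.documents):
            raise DuplicateKeyError("duplicate doc_id in corpus")
        for m in self.mentions:
            doc = by_id.get(m.doc_id)
            if doc is None:
                raise DanglingAnnotationError(
                    f"annotation for unknown doc_id {m.doc_id!r}"
                )
            m.check_against(doc)
        ordered = tuple(sorted(self.mentions, key=lambda m: (m.doc_id, m.start, m.end)))
        object.__setattr__(self, "mentions", ordered)

    @property
    def documents_by_id(self) -> dict[str, Document]:
        return {d.doc_id: d for d in self.documents}

    def mentions_of(self, doc_id: str) -> tuple[Mention, ...]:
        return tuple(m for m in self.mentions if m.doc_id == doc_id)


# ---------------------------------------------------------------------------
# PubTator-style corpus format
# ---------------------------------------------------------------------------

def read_pubtator(text: str) -> AnnotatedCorpus:
    """Parse PubTator-style text into a validated corpus.

    Blocks are ``docid|t|title`` then ``docid|a|abstract`` lines followed by
    tab-separated annotation lines ``docid⇥start⇥end⇥surface⇥type⇥cui``,
    separated by blank lines.  Offsets are checked against the title-space-
    abstract concatenation; mismatches raise :class:`OffsetIntegrityError`.
    """
    documents: list[Document] = []
    mentions: list[Mention] = []
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    order: list[str] = []

    for line in text.splitlines():
        if not line.strip():
            continue
        if "|t|" in line and "\t" not in line.split("|t|", 1)[0]:
            doc_id, title = line.split("|t|", 1)
            if doc_id in titles:
                raise DuplicateKeyError(f"duplicate title line for {doc_id!r}")
            titles[doc_id] = title
            order.append(doc_id)
            continue
        if "|a|" in line and "\t" not in line.split("|a|", 1)[0]:
            doc_id, abstract = line.split("|a|", 1)
            abstracts[doc_id] = abstract
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise DanglingAnnotationError(
                f"annotation line with {len(parts)} fields (need 6): {line!r}"
            )
        doc_id, start, end, surface, declared, cui = parts[:6]
        mentions.append(
            Mention(
                doc_id=doc_id,
                start=int(start),
                end=int(end),
                surface=surface,
                gold_cui=cui if cui and cui != "-" else None,
                declared_type=declared or None,
            )
        )

    for doc_id in order:
        documents.append(
            Document(doc_id=doc_id, title=titles[doc_id], abstract=abstracts.get(doc_id, ""))
        )
    return AnnotatedCorpus(tuple(documents), tuple(mentions))


def write_pubtator(corpus: AnnotatedCorpus) -> str:
    """Serialize a corpus; ``read_pubtator(write_pubtator(c))`` round-trips."""
    blocks: list[str] = []
    mentions_by_doc: dict[str, list[Mention]] = {}
    for m in corpus.mentions:
        mentions_by_doc.setdefault(m.doc_id, []).append(m)
    for doc in corpus.documents:
        lines = [f"{doc.doc_id}|t|{doc.title}", f"{doc.doc_id}|a|{doc.abstract}"]
        for m in mentions_by_doc.get(doc.doc_id, []):
            lines.append(
                "\t".join(
                    [
                        m.doc_id,
                        str(m.start),
                        str(m.end),
                        m.surface,
                        m.declared_type or "-",
                        m.gold_cui or "-",
                    ]
                )
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def assign_gold_groups(
    corpus: AnnotatedCorpus, inventory: ConceptInventory, scheme: TypeScheme
) -> AnnotatedCorpus:
    """Recompute every mention's gold groups from its gold CUI.

    The annotation type column is advisory only; group labels are always
    derived CUI -> fine types -> groups.  Mentions whose gold CUI is absent
    from the inventory get empty gold_groups and count as unlinkable
    downstream.
    """
    out = []
    for m in corpus.mentions:
        if m.gold_cui is not None and m.gold_cui in inventory:
            groups = scheme.groups_of_concept(inventory[m.gold_cui].fine_types)
        else:
            groups = frozenset()
        out.append(replace(m, gold_groups=groups))
    return AnnotatedCorpus(corpus.documents, tuple(out))


# ---------------------------------------------------------------------------
# Concept inventory TSV
# ---------------------------------------------------------------------------

_INV_HEADER = ["cui", "preferred_name", "synonyms", "fine_types"]


def read_inventory(text: str) -> ConceptInventory:
    """Read a four-column inventory TSV (synonyms/types pipe-separated)."""
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != _INV_HEADER:
        raise InvalidEntryError(
            "inventory TSV must start with header " + "\\t".join(_INV_HEADER)
        )
    entries: list[ConceptEntry] = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise InvalidEntryError(f"line {i}: expected 4 columns, got {len(parts)}")
        cui, name, syns, types = parts
        fine_types = frozenset(t for t in types.split("|") if t)
        if not fine_types:
            raise InvalidEntryError(f"line {i}: concept {cui!r} has no fine types")
        entries.append(
            ConceptEntry(
                cui=cui,
                preferred_name=name,
                synonyms=tuple(s for s in syns.split("|") if s),
                fine_types=fine_types,
            )
        )
    return ConceptInventory.from_entries(entries)


def write_inventory(inventory: ConceptInventory) -> str:
    lines = ["\t".join(_INV_HEADER)]
    for cui in inventory.entries:
        e = inventory[cui]
        lines.append(
            "\t".join(
                [e.cui, e.preferred_name, "|".join(e.synonyms), "|".join(sorted(e.fine_types))]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Candidate JSON-lines
# ---------------------------------------------------------------------------

def read_candidates(text: str, *, allow_unsorted: bool = False) -> tuple[CandidateList, ...]:
    """Read candidate lists from JSON-lines.

    Each record: ``{"doc_id", "start", "end", "surface", "candidates":
    [[cui, score], ...], "provenance"}``.  Non-monotone scores raise an
    :class:`OrderingError` unless ``allow_unsorted`` is set, in which case
    the list is re-sorted (stable, by descending score) with a warning.
    """
    out: list[CandidateList] = []
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        rec = json.loads(line)
        mention = Mention(
            doc_id=rec["doc_id"],
            start=rec["start"],
            end=rec["end"],
            surface=rec.get("surface", ""),
        )
        cands = [(str(c), float(s)) for c, s in rec["candidates"]]
        scores = [s for _, s in cands]
        if any(a < b for a, b in zip(scores, scores[1:])):
            if not allow_unsorted:
                raise OrderingError(f"record {i}: scores not non-increasing")
            warnings.warn(f"record {i}: re-sorting unsorted candidate scores")
            cands = sorted(cands, key=lambda cs: -cs[1])
        out.append(
            CandidateList(
                mention=mention,
                candidates=tuple(cands),
                provenance=rec.get("provenance", "imported"),
            )
        )
    return tuple(out)


def write_candidates(lists: Iterable[CandidateList]) -> str:
    lines = []
    for cl in lists:
        lines.append(
            json.dumps(
                {
                    "doc_id": cl.mention.doc_id,
                    "start": cl.mention.start,
                    "end": cl.mention.end,
                    "surface": cl.mention.surface,
                    "candidates": [[c, s] for c, s in cl.candidates],
                    "provenance": cl.provenance,
                },
                ensure_ascii=False,
                sort_keys=True,
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
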