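"""Distant supervision from MeSH headers.

PubMed articles carry manually assigned Medical Subject Headings (MeSH).
Given detected mention spans and a crosswalk from header names to concept
identifiers and fine types, a mention is weakly linked if and only if its
surface exactly matches one of its own document's headers.  The rule trades
recall for precision: most true mentions are missed (surface variation,
headers not mentioned verbatim), but those that are linked are almost
always right — exactly the regime that makes the output usable as silver
training data for type prediction.

"Exactly matches" defaults to case-insensitive comparison after whitespace
collapsing (headers are Title Case while running text is mixed-case; a
strictly literal comparison would link almost nothing).  A strict
case-sensitive mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .corpus_io import AnnotatedCorpus, Document, Mention
from .errors import InvalidEntryError, NoOverlapError, UndefinedMetricError
from .linking import normalize_surface
from .typescheme import TypeScheme

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrosswalkEntry:
    header: str
    mesh_id: str
    cui: str
    fine_types: frozenset[str]


@dataclass(frozen=True)
class MeshCrosswalk:
    """Normalized MeSH header name -> (mesh_id, cui, fine_types)."""

    entries: Mapping[str, CrosswalkEntry]

    @classmethod
    def from_entries(
        cls, entries: Sequence[CrosswalkEntry], *, case_sensitive: bool = False
    ) -> "MeshCrosswalk":
        key = (lambda s: " ".join(s.split())) if case_sensitive else normalize_surface
        out: dict[str, CrosswalkEntry] = {}
        for e in entries:
            k = key(e.header)
            if k in out:
                raise InvalidEntryError(f"duplicate header after normalization: {k!r}")
            out[k] = e
        return cls(out)

    def __contains__(self, key: str) -> bool:
        return key in self.entries


_XWALK_HEADER = ["header", "mesh_id", "cui", "fine_types"]


def read_crosswalk(text: str, *, case_sensitive: bool = False) -> MeshCrosswalk:
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != _XWALK_HEADER:
        raise InvalidEntryError(
            "crosswalk TSV must start with header " + "\\t".join(_XWALK_HEADER)
        )
    entries = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise InvalidEntryError(f"line {i}: expected 4 columns")
        header, mesh_id, cui, types = parts
        entries.append(
            CrosswalkEntry(
                header=header,
                mesh_id=mesh_id,
                cui=cui,
                fine_types=frozenset(t for t in types.split("|") if t),
            )
        )
    return MeshCrosswalk.from_entries(entries, case_sensitive=case_sensitive)


def write_crosswalk(xwalk: MeshCrosswalk) -> str:
    lines = ["\t".join(_XWALK_HEADER)]
    for e in xwalk.entries.values():
        lines.append(
            "\t".join([e.header, e.mesh_id, e.cui, "|".join(sorted(e.fine_types))])
        )
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class WeakCorpus:
    """Distantly supervised corpus plus coverage bookkeeping."""

    corpus: AnnotatedCorpus  # only the linked mentions
    n_detected: int
    n_linked: int
    n_headers_skipped: int  # matched headers absent from the crosswalk

    @property
    def coverage(self) -> float:
        return self.n_linked / self.n_detected if self.n_detected else 0.0


def weak_annotate(
    documents: Sequence[Document],
    mentions: Sequence[Mention],
    xwalk: MeshCrosswalk,
    scheme: TypeScheme,
    *,
    case_sensitive: bool = False,
) -> WeakCorpus:
    """Link detected mentions whose surface exactly matches a document header.

    Each document's headers are tried in their given order; the first match
    wins.  Matched headers missing from the crosswalk are skipped and
    counted, never raised.  Mentions that match no header are dropped from
    the weak corpus.
    """
    norm = (lambda s: " ".join(s.split())) if case_sensitive else normalize_surface
    docs_by_id = {d.doc_id: d for d in documents}
    linked: list[Mention] = []
    n_skipped = 0
    for m in mentions:
        doc = docs_by_id.get(m.doc_id)
        if doc is None or not doc.mesh_headers:
            continue
        surface_n = norm(m.surface)
        for header in doc.mesh_headers:
            if norm(header) != surface_n:
                continue
            key = norm(header)
            if key not in xwalk:
                n_skipped += 1
                logger.info("header %r matched but absent from crosswalk", header)
                break
            entry = xwalk.entries[key]
            linked.append(
                replace(
                    m,
                    gold_cui=entry.cui,
                    gold_groups=scheme.groups_of_concept(
                        t for t in entry.fine_types if t in scheme
                    ),
                )
            )
            break  # first-match-wins
    corpus = AnnotatedCorpus(tuple(documents), tuple(linked))
    return WeakCorpus(
        corpus=corpus,
        n_detected=len(mentions),
        n_linked=len(linked),
        n_headers_skipped=n_skipped,
    )


def assess_weak_quality(
    weak: WeakCorpus,
    gold: AnnotatedCorpus,
    *,
    relaxed_overlap: bool = False,
) -> tuple[float, float]:
    """Precision/recall of weak links against gold annotations on shared docs.

    A weak link is correct iff a gold mention with identical span and CUI
    exists (strict mode); ``relaxed_overlap`` instead accepts any
    overlapping gold span with the same CUI.
    """
    shared = {d.doc_id for d in weak.corpus.documents} & {
        d.doc_id for d in gold.documents
    }
    if not shared:
        raise NoOverlapError("weak and gold corpora share no documents")
    weak_m = [m for m in weak.corpus.mentions if m.doc_id in shared]
    gold_m = [m for m in gold.mentions if m.doc_id in shared and m.gold_cui]
    if not weak_m:
        raise UndefinedMetricError("precision undefined: zero weak links on shared docs")

    gold_exact = {(m.span_key, m.gold_cui) for m in gold_m}
    correct = 0
    for m in weak_m:
        if (m.span_key, m.gold_cui) in gold_exact:
            correct += 1
        elif relaxed_overlap and any(
            g.doc_id == m.doc_id
            and g.gold_cui == m.gold_cui
            and min(g.end, m.end) > max(g.start, m.start)
            for g in gold_m
        ):
            correct += 1
    precision = correct / len(weak_m)
    recall = correct / len(gold_m) if gold_m else 0.0
    return precision, recall
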