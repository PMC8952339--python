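"""Coarse semantic grouping of UMLS fine semantic types.

The UMLS Metathesaurus assigns each concept one or more of 127 fine
semantic types (e.g. ``Clinical Drug``, ``Sign or Symptom``).  Fine types
are both multi-valued per concept and heavily skewed in frequency, which
makes them awkward direct targets for type prediction.  This module houses
the static mapping of the 127 fine types onto 24 coarse semantic groups
used as the label space for prediction and candidate filtering, plus the
distinguished ``None`` label reserved for spurious mentions (a detected
span that refers to no medical concept at all).

The packaged table is a plain two-column TSV; custom typologies can be
loaded from user TSVs with the strict cardinality check disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import DuplicateKeyError, InvalidSchemeError, UnknownTypeError

#: Reserved label for spurious mentions; never a group and never a fine type.
NONE_LABEL = "None"

#: Cardinalities of the packaged scheme.
N_FINE_TYPES = 127
N_GROUPS = 24

_BUILTIN_RESOURCE = "semantic_groups.tsv"


@dataclass(frozen=True)
class TypeScheme:
    """A total, single-valued map from fine semantic types to coarse groups.

    Attributes
    ----------
    entries
        Mapping fine-type name -> group name.  Names are matched exactly
        (after trimming outer whitespace); no case folding is applied, so
        transcription errors in type names surface as unknown-type errors
        instead of being papered over.
    group_names
        Group labels in first-seen (table) order.
    none_label
        The reserved label for spurious mentions, distinct from all groups.
    """

    entries: dict[str, str]
    group_names: tuple[str, ...] = field(default=())
    none_label: str = NONE_LABEL

    def __post_init__(self) -> None:
        if not self.group_names:
            seen: list[str] = []
            for g in self.entries.values():
                if g not in seen:
                    seen.append(g)
            object.__setattr__(self, "group_names", tuple(seen))
        if self.none_label in self.group_names:
            raise InvalidSchemeError(
                f"reserved label {self.none_label!r} cannot be a group"
            )
        if self.none_label in self.entries:
            raise InvalidSchemeError(
                f"reserved label {self.none_label!r} cannot be a fine type"
            )

    def __contains__(self, fine_type: str) -> bool:
        return fine_type in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def group_of(self, fine_type: str) -> str:
        """Return the unique group of ``fine_type``.

        Raises
        ------
        UnknownTypeError
            If ``fine_type`` is not part of the scheme.  An unknown type is
            never mapped silently to ``None``.
        """
        try:
            return self.entries[fine_type]
        except KeyError:
            raise UnknownTypeError(
                f"unknown fine semantic type: {fine_type!r}"
            ) from None

    def groups_of_concept(self, fine_types: Iterable[str]) -> frozenset[str]:
        """Union of groups over a concept's fine types (empty in, empty out)."""
        return frozenset(self.group_of(t) for t in fine_types)


def load_scheme(source: str | Path | None = None, *, strict: bool = True) -> TypeScheme:
    """Load a type scheme from the packaged table or a two-column TSV.

    Parameters
    ----------
    source
        ``None`` (or ``"builtin"``) for the packaged 127-type / 24-group
        table; otherwise a path to a TSV with header ``fine_type<TAB>group``.
    strict
        Enforce the packaged cardinalities (127 fine types, 24 groups).
        Disable for custom typologies.
    """
    if source is None or source == "builtin":
        text = (
            resources.files("medlink.data").joinpath(_BUILTIN_RESOURCE).read_text("utf-8")
        )
    else:
        text = Path(source).read_text("utf-8")
    return parse_scheme(text, strict=strict)


def parse_scheme(text: str, *, strict: bool = True) -> TypeScheme:
    """Parse TSV text into a validated :class:`TypeScheme`."""
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != ["fine_type", "group"]:
        raise InvalidSchemeError("scheme TSV must start with header 'fine_type\\tgroup'")
    entries: dict[str, str] = {}
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InvalidSchemeError(f"line {i}: expected 2 tab-separated columns")
        fine, group = parts[0].strip(), parts[1].strip()
        if not fine or not group:
            raise InvalidSchemeError(f"line {i}: empty fine type or group")
        if group == NONE_LABEL:
            raise InvalidSchemeError(
                f"line {i}: fine type {fine!r} mapped to reserved label {NONE_LABEL!r}"
            )
        if fine in entries:
            raise DuplicateKeyError(f"line {i}: duplicate fine type {fine!r}")
        entries[fine] = group
    scheme = TypeScheme(entries)
    if strict:
        if len(scheme.entries) != N_FINE_TYPES:
            raise InvalidSchemeError(
                f"strict scheme requires {N_FINE_TYPES} fine types, got {len(scheme.entries)}"
            )
        if len(scheme.group_names) != N_GROUPS:
            raise InvalidSchemeError(
                f"strict scheme requires {N_GROUPS} groups, got {len(scheme.group_names)}"
            )
    return scheme


def write_scheme(scheme: TypeScheme) -> str:
    """Serialize a scheme to TSV text (inverse of :func:`parse_scheme`)."""
    lines = ["fine_type\tgroup"]
    lines.extend(f"{fine}\t{group}" for fine, group in scheme.entries.items())
    return "\n".join(lines) + "\n"
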