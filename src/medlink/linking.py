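"""The three-stage linking pipeline: generate, filter by type, select.

Candidate generation over-generates by design — every concept whose name or
synonym matches the mention surface is a candidate ("cold" pulls in the
common-cold disease, cold temperature, and a cold-brand drug).  The
filtering stage prunes candidates whose semantic types are incompatible
with the group predicted for the mention from its context; the final
selection takes the highest-ranked survivor.

Filtering uses intersection semantics: a candidate survives when its type
set (fine types, or their groups under coarse granularity) intersects the
predicted set.  With a multi-label prediction and multi-type concepts this
is the only rule that guarantees oracle safety — filtering on the gold
concept's own types can never remove a gold candidate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .corpus_io import (
    AnnotatedCorpus,
    CandidateList,
    ConceptInventory,
    Mention,
)
from .errors import ConfigError, DanglingCandidateError
from .typepred import (
    ThresholdSet,
    TypePredictor,
    featurize_context,
    oracle_predict,
    predict_groups,
)
from .typescheme import TypeScheme

#: Default candidate-list cap, matching common dictionary linkers.
DEFAULT_MAX_CANDIDATES = 5

_WS = re.compile(r"\s+")


def normalize_surface(s: str) -> str:
    """Lowercase and collapse internal whitespace (default lexicon key)."""
    return _WS.sub(" ", s.strip().lower())


@dataclass(frozen=True)
class Lexicon:
    """Normalized surface form -> ranked (cui, score) list."""

    forms: Mapping[str, tuple[tuple[str, float], ...]]

    def lookup(self, surface: str) -> tuple[tuple[str, float], ...]:
        return self.forms.get(normalize_surface(surface), ())


def build_lexicon(
    inventory: ConceptInventory,
    normalizer: Callable[[str], str] = normalize_surface,
) -> Lexicon:
    """Index preferred names and synonyms of every concept.

    A form shared by n concepts yields n candidates each scored 1/n, with
    ties broken by CUI lexicographic order — ambiguity is preserved, not
    resolved, at this stage.
    """
    by_form: dict[str, set[str]] = {}
    for cui in inventory.entries:
        for name in inventory[cui].all_names:
            by_form.setdefault(normalizer(name), set()).add(cui)
    forms = {
        form: tuple((cui, 1.0 / len(cuis)) for cui in sorted(cuis))
        for form, cuis in by_form.items()
    }
    return Lexicon(forms)


def generate_candidates(
    mention: Mention,
    lexicon: Lexicon,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> CandidateList:
    """Dictionary lookup of the normalized surface, capped at max_candidates."""
    if max_candidates < 1:
        raise ConfigError(f"max_candidates must be >= 1, got {max_candidates}")
    return CandidateList(
        mention=mention,
        candidates=lexicon.lookup(mention.surface)[:max_candidates],
        provenance="dictionary",
    )


def filter_candidates(
    cands: CandidateList,
    predicted: Iterable[str],
    inventory: ConceptInventory,
    scheme: TypeScheme,
    granularity: str = "coarse",
    empty_policy: str = "drop",
) -> CandidateList:
    """Keep candidates whose type set intersects the predicted set.

    Order and scores are preserved.  If no candidate survives, the
    ``empty_policy`` decides: ``drop`` returns an empty list (the mention is
    later excluded), ``passthrough`` returns the original list unchanged.
    An empty predicted set (the None type) keeps nothing under ``drop``.
    """
    if granularity not in ("fine", "coarse"):
        raise ConfigError(f"granularity must be fine|coarse, got {granularity!r}")
    if empty_policy not in ("drop", "passthrough"):
        raise ConfigError(f"empty_policy must be drop|passthrough, got {empty_policy!r}")
    predicted = frozenset(predicted)
    kept = []
    for cui, score in cands.candidates:
        if cui not in inventory:
            raise DanglingCandidateError(f"candidate cui {cui!r} not in inventory")
        types = inventory[cui].fine_types
        cand_set = types if granularity == "fine" else scheme.groups_of_concept(types)
        if cand_set & predicted:
            kept.append((cui, score))
    if not kept and empty_policy == "passthrough":
        return cands
    return CandidateList(
        mention=cands.mention, candidates=tuple(kept), provenance=cands.provenance
    )


@dataclass(frozen=True)
class LinkingResult:
    """Per-mention outcome of the full pipeline."""

    mention: Mention
    unfiltered: CandidateList
    predicted_groups: frozenset[str] | None  # None when filtering is off
    filtered: CandidateList
    selected_cui: str | None
    suppressed: bool  # predicted type set was empty (None-type mention)

    def __post_init__(self) -> None:
        unf = set(self.unfiltered.cuis)
        if not set(self.filtered.cuis) <= unf:
            raise ConfigError("filtered candidates must be a subset of unfiltered")


def link_corpus(
    corpus: AnnotatedCorpus,
    inventory: ConceptInventory,
    scheme: TypeScheme,
    *,
    candidates: Mapping[tuple[str, int, int], CandidateList] | None = None,
    lexicon: Lexicon | None = None,
    predictor: TypePredictor | None = None,
    thresholds: ThresholdSet | None = None,
    mode: str = "predictor",
    granularity: str = "coarse",
    empty_policy: str = "drop",
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> list[LinkingResult]:
    """Run candidate generation, type filtering, and selection per mention.

    ``mode`` selects the type source: ``predictor`` (trained model +
    thresholds), ``oracle-fine`` / ``oracle-coarse`` (gold CUI's own types),
    or ``off`` (no filtering; the unfiltered top candidate is selected).
    Candidate lists may be supplied per mention span; missing spans fall
    back to the built-in lexicon generator (an absent lexicon means an
    empty candidate list).
    """
    if mode not in ("predictor", "oracle-fine", "oracle-coarse", "off"):
        raise ConfigError(f"unknown mode {mode!r}")
    if mode == "predictor" and (predictor is None or thresholds is None):
        raise ConfigError("mode='predictor' requires a predictor and thresholds")
    if lexicon is None and candidates is None:
        lexicon = build_lexicon(inventory)
    docs = corpus.documents_by_id
    results: list[LinkingResult] = []
    for m in corpus.mentions:
        if candidates is not None and m.span_key in candidates:
            unfiltered = candidates[m.span_key]
        elif lexicon is not None:
            unfiltered = generate_candidates(m, lexicon, max_candidates)
        else:
            unfiltered = CandidateList(mention=m, candidates=(), provenance="missing")

        if mode == "off":
            predicted = None
            filtered = unfiltered
        else:
            if mode == "predictor":
                ex = featurize_context(docs[m.doc_id], m, predictor.config.window_k)
                predicted = predict_groups(predictor, thresholds, ex)
                gran = granularity
            else:
                gran = "fine" if mode == "oracle-fine" else "coarse"
                predicted = oracle_predict(m, inventory, scheme, gran)
            filtered = filter_candidates(
                unfiltered, predicted, inventory, scheme, gran, empty_policy
            )
        selected = filtered.cuis[0] if filtered.cuis else None
        results.append(
            LinkingResult(
                mention=m,
                unfiltered=unfiltered,
                predicted_groups=predicted,
                filtered=filtered,
                selected_cui=selected,
                suppressed=(predicted is not None and not predicted),
            )
        )
    return results


def results_to_jsonl(results: Sequence[LinkingResult]) -> str:
    """Serialize linking results as JSON-lines (stable key order)."""
    import json

    lines = []
    for r in results:
        lines.append(
            json.dumps(
                {
                    "doc_id": r.mention.doc_id,
                    "start": r.mention.start,
                    "end": r.mention.end,
                    "surface": r.mention.surface,
                    "gold_cui": r.mention.gold_cui,
                    "gold_groups": (
                        sorted(r.mention.gold_groups)
                        if r.mention.gold_groups is not None
                        else None
                    ),
                    "unfiltered": [[c, s] for c, s in r.unfiltered.candidates],
                    "predicted_groups": (
                        sorted(r.predicted_groups)
                        if r.predicted_groups is not None
                        else None
                    ),
                    "filtered": [[c, s] for c, s in r.filtered.candidates],
                    "selected_cui": r.selected_cui,
                    "suppressed": r.suppressed,
                },
                ensure_ascii=False,
                sort_keys=True,
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def results_from_jsonl(text: str) -> list[LinkingResult]:
    """Inverse of :func:`results_to_jsonl`."""
    import json

    out: list[LinkingResult] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        mention = Mention(
            doc_id=rec["doc_id"],
            start=rec["start"],
            end=rec["end"],
            surface=rec["surface"],
            gold_cui=rec.get("gold_cui"),
            gold_groups=(
                frozenset(rec["gold_groups"]) if rec.get("gold_groups") is not None else None
            ),
        )
        unfiltered = CandidateList(
            mention=mention,
            candidates=tuple((c, float(s)) for c, s in rec["unfiltered"]),
        )
        filtered = CandidateList(
            mention=mention,
            candidates=tuple((c, float(s)) for c, s in rec["filtered"]),
        )
        out.append(
            LinkingResult(
                mention=mention,
                unfiltered=unfiltered,
                predicted_groups=(
                    frozenset(rec["predicted_groups"])
                    if rec.get("predicted_groups") is not None
                    else None
                ),
                filtered=filtered,
                selected_cui=rec.get("selected_cui"),
                suppressed=bool(rec.get("suppressed", False)),
            )
        )
    return out
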