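"""Entity-linking metrics, type-prediction reports, reduction analytics.

Two linking metrics are provided:

* **Exact** mention+ID match: a prediction is a true positive only when its
  span and concept identifier both match a gold annotation exactly.
* **Partial** mention+ID match: overlapping spans with a matching concept
  identifier earn fractional credit ``w = overlap_chars / max(len_pred,
  len_gold)``, with greedy one-to-one matching by descending weight.  The
  weight convention (normalizing by the longer span) is this package's
  documented choice; it is symmetric-penalizing, bounded by 1, and reduces
  to the exact metric on exact spans, so partial scores never fall below
  exact ones.

Type predictions are scored one-vs-rest per group with micro/macro
aggregates, plus a gold-vs-predicted confusion ranking.  The reduction
report quantifies how much type filtering shrinks candidate sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import DuplicateKeyError, UndefinedMetricError
from .corpus_io import AnnotatedCorpus, ConceptInventory
from .linking import LinkingResult

SpanKey = tuple[str, int, int]
Prediction = tuple[SpanKey, str]


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float
    tp_weight: float
    n_pred: int
    n_gold: int

    @classmethod
    def from_counts(cls, tp_weight: float, n_pred: int, n_gold: int) -> "PRF":
        p = tp_weight / n_pred if n_pred else 0.0
        r = tp_weight / n_gold if n_gold else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) else 0.0
        return cls(p, r, f1, tp_weight, n_pred, n_gold)


def _check_unique_spans(items: Sequence[Prediction], what: str) -> None:
    keys = [k for k, _ in items]
    if len(set(keys)) != len(keys):
        raise DuplicateKeyError(f"duplicate (doc, start, end) span in {what}")


def exact_f1(pred: Sequence[Prediction], gold: Sequence[Prediction]) -> PRF:
    """Strict mention+ID F1: span and CUI must both match exactly."""
    _check_unique_spans(pred, "predictions")
    _check_unique_spans(gold, "gold")
    if not gold:
        raise UndefinedMetricError("recall undefined: empty gold set")
    gold_set = set(gold)
    tp = sum(1 for item in pred if item in gold_set)
    return PRF.from_counts(float(tp), len(pred), len(gold))


def _overlap(a: SpanKey, b: SpanKey) -> int:
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


def partial_f1(pred: Sequence[Prediction], gold: Sequence[Prediction]) -> PRF:
    """Overlap-weighted mention+ID F1 with greedy one-to-one matching.

    Candidate pairs are same-document span overlaps with equal CUI; each
    pair's weight is ``overlap / max(len_pred, len_gold)``.  Pairs are
    matched greedily by descending weight (ties: earlier gold start, then
    earlier pred start) so no span is credited twice.
    """
    _check_unique_spans(pred, "predictions")
    _check_unique_spans(gold, "gold")
    if not gold:
        raise UndefinedMetricError("recall undefined: empty gold set")
    pairs = []
    for pi, (pk, pc) in enumerate(pred):
        for gi, (gk, gc) in enumerate(gold):
            if pc != gc:
                continue
            ov = _overlap(pk, gk)
            if ov <= 0:
                continue
            w = ov / max(pk[2] - pk[1], gk[2] - gk[1])
            pairs.append((w, gk[0], gk[1], pk[1], pi, gi))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    tp_weight = 0.0
    for w, _, _, _, pi, gi in pairs:
        if pi in used_p or gi in used_g:
            continue
        used_p.add(pi)
        used_g.add(gi)
        tp_weight += w
    return PRF.from_counts(tp_weight, len(pred), len(gold))


# ---------------------------------------------------------------------------
# Type-prediction reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupReport:
    per_group: Mapping[str, PRF]
    micro: PRF
    macro_f1: float


def per_group_f1(
    predicted: Sequence[Iterable[str]],
    gold: Sequence[Iterable[str]],
    groups: Sequence[str] | None = None,
) -> GroupReport:
    """One-vs-rest PRF per group with micro (pooled) and macro aggregates."""
    if len(predicted) != len(gold):
        raise UndefinedMetricError("predicted and gold have different lengths")
    pred_sets = [frozenset(p) for p in predicted]
    gold_sets = [frozenset(g) for g in gold]
    if groups is None:
        groups = sorted(set().union(*pred_sets, *gold_sets)) if pred_sets else []
    per: dict[str, PRF] = {}
    tp_all = np_all = ng_all = 0
    for g in groups:
        tp = sum(1 for p, t in zip(pred_sets, gold_sets) if g in p and g in t)
        n_pred = sum(1 for p in pred_sets if g in p)
        n_gold = sum(1 for t in gold_sets if g in t)
        per[g] = PRF.from_counts(float(tp), n_pred, n_gold)
        tp_all += tp
        np_all += n_pred
        ng_all += n_gold
    micro = PRF.from_counts(float(tp_all), np_all, ng_all)
    macro = sum(v.f1 for v in per.values()) / len(per) if per else 0.0
    return GroupReport(per, micro, macro)


def confusion_pairs(
    predicted: Sequence[Iterable[str]],
    gold: Sequence[Iterable[str]],
) -> list[tuple[str, str, int]]:
    """Count (gold group, wrongly predicted group) pairs, sorted descending.

    Only predictions outside the gold set count as confusions.
    """
    counts: dict[tuple[str, str], int] = {}
    for p, t in zip(predicted, gold):
        p, t = frozenset(p), frozenset(t)
        for g in t:
            for q in p - t:
                counts[(g, q)] = counts.get((g, q), 0) + 1
    return sorted(
        [(g, q, n) for (g, q), n in counts.items()], key=lambda x: (-x[2], x[0], x[1])
    )


# ---------------------------------------------------------------------------
# Candidate-reduction analytics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReductionRecord:
    span: SpanKey
    unfiltered_size: int
    filtered_size: int
    gold_present: bool  # gold CUI appears in the unfiltered list
    gold_retained: bool  # gold CUI still appears after filtering
    type_correct: bool | None  # predicted groups intersect gold groups


@dataclass(frozen=True)
class ReductionReport:
    records: tuple[ReductionRecord, ...]
    histogram: Mapping[int, int]  # filtered size -> count (sizes >= 5 pooled at 5)
    fraction_reduced: float
    fraction_fully_disambiguated: float  # |filtered| == 1 with gold retained
    n_gold_present: int


def reduction_report(results: Sequence[LinkingResult]) -> ReductionReport:
    """Summarize candidate-set shrinkage across linking results."""
    records = []
    hist: dict[int, int] = {}
    n_reduced = 0
    n_solved = 0
    n_present = 0
    for r in results:
        gold = r.mention.gold_cui
        present = gold is not None and gold in r.unfiltered.cuis
        retained = gold is not None and gold in r.filtered.cuis
        tc: bool | None = None
        if r.predicted_groups is not None and r.mention.gold_groups is not None:
            tc = bool(r.predicted_groups & r.mention.gold_groups)
        records.append(
            ReductionRecord(
                span=r.mention.span_key,
                unfiltered_size=len(r.unfiltered),
                filtered_size=len(r.filtered),
                gold_present=present,
                gold_retained=retained,
                type_correct=tc,
            )
        )
        bucket = min(len(r.filtered), 5)
        hist[bucket] = hist.get(bucket, 0) + 1
        if len(r.filtered) < len(r.unfiltered):
            n_reduced += 1
        if present:
            n_present += 1
            if len(r.filtered) == 1 and retained:
                n_solved += 1
    n = len(records)
    return ReductionReport(
        records=tuple(records),
        histogram=hist,
        fraction_reduced=n_reduced / n if n else 0.0,
        fraction_fully_disambiguated=n_solved / n_present if n_present else 0.0,
        n_gold_present=n_present,
    )


# ---------------------------------------------------------------------------
# Adapters
# ---------------------------------------------------------------------------

def gold_from_corpus(
    corpus: AnnotatedCorpus, inventory: ConceptInventory | None = None
) -> tuple[list[Prediction], int]:
    """Gold (span, cui) pairs; mentions whose CUI is outside the inventory
    are excluded (unlinkable) and counted separately."""
    gold: list[Prediction] = []
    n_unlinkable = 0
    for m in corpus.mentions:
        if m.gold_cui is None:
            continue
        if inventory is not None and m.gold_cui not in inventory:
            n_unlinkable += 1
            continue
        gold.append((m.span_key, m.gold_cui))
    return gold, n_unlinkable


def predictions_from_results(results: Sequence[LinkingResult]) -> list[Prediction]:
    """Selected (span, cui) pairs; abstentions and suppressions are
    non-predictions (they cost recall, not precision)."""
    return [
        (r.mention.span_key, r.selected_cui)
        for r in results
        if r.selected_cui is not None
    ]
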