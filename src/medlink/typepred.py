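"""Semantic-group prediction for mentions in context.

A mention's group (e.g. whether "cold" is being used as a disease, a
natural phenomenon, or a drug) is predictable from its usage: the tokens
around it.  The contract here is:

* a context window of ``k`` tokens on each side, with the mention bracketed
  by the special marker tokens ``[men]`` and ``[/men]`` carrying its
  position;
* a trainable multi-label classifier emitting one probability per group of
  the scheme;
* per-group decision thresholds tuned by grid search on a validation split;
* the empty predicted set denoting the ``None`` type (spurious mention).

The default encoder is a hashed bag-of-tokens over three namespaces (left
context, mention, right context) feeding one-vs-rest logistic scorers.  It
is deliberately lightweight — deterministic, CPU-only, dependency-free
beyond scikit-learn — and any stronger contextual encoder (e.g. a
transformer) can be dropped in behind the same featurize/score contract.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.feature_extraction import FeatureHasher
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score

from .corpus_io import AnnotatedCorpus, ConceptInventory, Document, Mention
from .errors import (
    ConfigError,
    DegenerateTrainingError,
    OracleUnavailableError,
    UndefinedMetricError,
    UnknownGroupError,
)
from .typescheme import TypeScheme

MEN_OPEN = "[men]"
MEN_CLOSE = "[/men]"

ARTIFACT_VERSION = 1

_PUNCT = string.punctuation


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization with punctuation stripped at token edges."""
    out = []
    for raw in text.split():
        tok = raw.strip(_PUNCT)
        if tok:
            out.append(tok)
    return out


@dataclass(frozen=True)
class ContextExample:
    """A mention in its context window, ready for featurization.

    ``tokens`` has the form ``(left..., "[men]", mention..., "[/men]",
    right...)`` with at most ``window_k`` tokens on each side.
    """

    tokens: tuple[str, ...]
    label_groups: frozenset[str] = frozenset()
    window_k: int = 0

    def __post_init__(self) -> None:
        if self.tokens.count(MEN_OPEN) != 1 or self.tokens.count(MEN_CLOSE) != 1:
            raise ConfigError("context must contain exactly one [men] and one [/men]")
        if self.tokens.index(MEN_OPEN) >= self.tokens.index(MEN_CLOSE):
            raise ConfigError("[men] must precede [/men]")

    def parts(self) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
        i, j = self.tokens.index(MEN_OPEN), self.tokens.index(MEN_CLOSE)
        return self.tokens[:i], self.tokens[i + 1 : j], self.tokens[j + 1 :]


def featurize_context(doc: Document, mention: Mention, k: int) -> ContextExample:
    """Build the context window for a mention.

    Tokenizes the text left of the span, the span itself, and the text right
    of the span separately, keeping at most ``k`` tokens on each side (fewer
    at document edges).  A mention whose surface strips to nothing is kept
    as its raw surface so the markers always bracket at least one token.
    """
    if k < 0:
        raise ConfigError(f"window k must be >= 0, got {k}")
    mention.check_against(doc)
    text = doc.text
    left = tokenize(text[: mention.start])
    right = tokenize(text[mention.end :])
    mid = tokenize(mention.surface) or [mention.surface]
    tokens = (
        tuple(left[len(left) - k :] if k else [])
        + (MEN_OPEN,)
        + tuple(mid)
        + (MEN_CLOSE,)
        + tuple(right[:k])
    )
    return ContextExample(
        tokens=tokens,
        label_groups=mention.gold_groups or frozenset(),
        window_k=k,
    )


def examples_from_corpus(
    corpus: AnnotatedCorpus, k: int
) -> list[tuple[Mention, ContextExample]]:
    """Featurize every mention of a corpus (gold groups become labels)."""
    docs = corpus.documents_by_id
    return [(m, featurize_context(docs[m.doc_id], m, k)) for m in corpus.mentions]


# ---------------------------------------------------------------------------
# Predictor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorConfig:
    """Training configuration; every run is a pure function of (data, config)."""

    window_k: int = 64  # context tokens per side; typical choices 48/64/128
    n_features: int = 2**18  # hashed feature-space width
    C: float = 1.0  # inverse L2 strength of the logistic scorers
    max_iter: int = 200
    seed: int = 0
    featurizer: str = "hashed-bow"

    def __post_init__(self) -> None:
        if self.window_k < 0 or self.n_features <= 0:
            raise ConfigError("window_k must be >= 0 and n_features positive")


def _example_features(ex: ContextExample) -> dict[str, float]:
    """Bag of tokens in three namespaces plus position-tagged nearest tokens.

    The tokens adjacent to the markers carry most of the type signal (the
    immediate collocates of the mention), so the two nearest tokens on each
    side get their own distance-tagged features on top of the plain bags.
    """
    left, mid, right = ex.parts()
    feats: dict[str, float] = {}
    for ns, toks in (("L", left), ("M", mid), ("R", right)):
        for tok in toks:
            key = f"{ns}:{tok.lower()}"
            feats[key] = feats.get(key, 0.0) + 1.0
    for d in (1, 2):
        if len(left) >= d:
            feats[f"L{d}:{left[-d].lower()}"] = 1.0
        if len(right) >= d:
            feats[f"R{d}:{right[d - 1].lower()}"] = 1.0
    return feats


class TypePredictor:
    """Multi-label semantic-group scorer over a fixed scheme.

    One probability per group; thresholding is applied separately (see
    :func:`tune_thresholds` / :func:`predict_groups`), so downstream code
    can trade precision against recall per group.
    """

    def __init__(
        self,
        scheme: TypeScheme,
        config: PredictorConfig,
        hasher: FeatureHasher,
        scorers: dict[str, object],
    ) -> None:
        self.scheme = scheme
        self.config = config
        self._hasher = hasher
        self._scorers = scorers  # group -> fitted LogisticRegression or float

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.scheme.group_names)

    def _matrix(self, examples: Sequence[ContextExample]):
        for ex in examples:
            if ex.window_k != self.config.window_k:
                warnings.warn(
                    f"example window_k={ex.window_k} differs from training "
                    f"window_k={self.config.window_k}"
                )
        return self._hasher.transform([_example_features(ex) for ex in examples])

    def predict_proba_many(
        self, examples: Sequence[ContextExample]
    ) -> np.ndarray:
        """Probability matrix of shape (n_examples, n_groups)."""
        X = self._matrix(examples)
        out = np.empty((len(examples), len(self.groups)))
        for j, g in enumerate(self.groups):
            scorer = self._scorers[g]
            if isinstance(scorer, float):
                out[:, j] = scorer
            else:
                out[:, j] = scorer.predict_proba(X)[:, 1]
        return out

    def predict_proba(self, ex: ContextExample) -> dict[str, float]:
        row = self.predict_proba_many([ex])[0]
        return dict(zip(self.groups, row.tolist()))

    def save(self, path) -> None:
        joblib.dump(
            {
                "format": "medlink-type-predictor",
                "version": ARTIFACT_VERSION,
                "config": self.config,
                "scheme_entries": dict(self.scheme.entries),
                "hasher": self._hasher,
                "scorers": self._scorers,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TypePredictor":
        blob = joblib.load(path)
        if blob.get("format") != "medlink-type-predictor":
            raise ConfigError(f"{path}: not a type-predictor artifact")
        scheme = TypeScheme(blob["scheme_entries"])
        return cls(scheme, blob["config"], blob["hasher"], blob["scorers"])


def train_predictor(
    train: Sequence[ContextExample],
    scheme: TypeScheme,
    config: PredictorConfig | None = None,
) -> TypePredictor:
    """Fit one-vs-rest group scorers on labeled context examples.

    Deterministic given (data order, config, seed).  A group with no
    positive (or no negative) training example gets a constant scorer equal
    to its clipped empirical rate, so the predictor always emits a full
    probability vector.
    """
    config = config or PredictorConfig()
    if not train:
        raise DegenerateTrainingError("empty training set")
    known = set(scheme.group_names)
    for ex in train:
        bad = ex.label_groups - known
        if bad:
            raise UnknownGroupError(f"label group(s) outside scheme: {sorted(bad)}")
    if all(not ex.label_groups for ex in train):
        raise DegenerateTrainingError("every training example has an empty label set")

    hasher = FeatureHasher(n_features=config.n_features, input_type="dict")
    X = hasher.transform([_example_features(ex) for ex in train])
    scorers: dict[str, object] = {}
    for g in scheme.group_names:
        y = np.array([1 if g in ex.label_groups else 0 for ex in train])
        if y.min() == y.max():  # single-class group: constant scorer
            scorers[g] = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
            continue
        clf = LogisticRegression(
            C=config.C,
            max_iter=config.max_iter,
            solver="liblinear",
            random_state=config.seed,
        )
        clf.fit(X, y)
        scorers[g] = clf
    return TypePredictor(scheme, config, hasher, scorers)


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSet:
    """Per-group decision thresholds in (0.001, 1)."""

    thresholds: Mapping[str, float]

    def __getitem__(self, group: str) -> float:
        return self.thresholds[group]


DEFAULT_GRID = tuple(np.linspace(0.001, 0.999, 100).tolist())


def _f1_at(scores: np.ndarray, labels: np.ndarray, thr: float) -> float:
    pred = scores >= thr
    tp = int(np.sum(pred & (labels == 1)))
    n_pred = int(pred.sum())
    n_pos = int((labels == 1).sum())
    if tp == 0:
        return 0.0
    p, r = tp / n_pred, tp / n_pos
    return 2 * p * r / (p + r)


def tune_thresholds(
    pred: TypePredictor,
    validation: Sequence[ContextExample],
    grid: Sequence[float] = DEFAULT_GRID,
) -> ThresholdSet:
    """Grid-search a per-group threshold maximizing per-group F1.

    Ties break toward the smallest maximizing threshold.  A group with no
    positive validation label defaults to 0.5 with a warning.
    """
    if any(not (0.001 <= g < 1) for g in grid):
        raise ConfigError("grid values must lie in [0.001, 1)")
    probs = pred.predict_proba_many(validation)
    chosen: dict[str, float] = {}
    for j, g in enumerate(pred.groups):
        labels = np.array([1 if g in ex.label_groups else 0 for ex in validation])
        if labels.sum() == 0:
            warnings.warn(f"group {g!r} absent from validation labels; threshold=0.5")
            chosen[g] = 0.5
            continue
        best_thr, best_f1 = None, -1.0
        for t in grid:
            f1 = _f1_at(probs[:, j], labels, t)
            if f1 > best_f1:
                best_thr, best_f1 = t, f1
        chosen[g] = float(best_thr)
    return ThresholdSet(chosen)


def predict_groups(
    pred: TypePredictor, thr: ThresholdSet, ex: ContextExample
) -> frozenset[str]:
    """Groups whose probability clears their threshold; empty = None type."""
    proba = pred.predict_proba(ex)
    return frozenset(g for g in pred.groups if proba[g] >= thr[g])


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def oracle_predict(
    mention: Mention,
    inventory: ConceptInventory,
    scheme: TypeScheme,
    granularity: str = "coarse",
) -> frozenset[str]:
    """Type prediction with gold knowledge: the gold concept's own types.

    ``fine`` returns the gold CUI's fine types; ``coarse`` their groups.
    Used to bound what type-based filtering can achieve.
    """
    if granularity not in ("fine", "coarse"):
        raise ConfigError(f"granularity must be fine|coarse, got {granularity!r}")
    if mention.gold_cui is None or mention.gold_cui not in inventory:
        raise OracleUnavailableError(
            f"{mention.span_key}: gold cui missing or unresolvable"
        )
    fine = inventory[mention.gold_cui].fine_types
    if granularity == "fine":
        return frozenset(fine)
    return scheme.groups_of_concept(fine)


# ---------------------------------------------------------------------------
# PR-AUC
# ---------------------------------------------------------------------------

def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall step curve (average precision)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ConfigError("scores and labels must have equal length")
    if labels.sum() == 0:
        raise UndefinedMetricError("PR-AUC undefined with zero positives")
    return float(average_precision_score(labels, scores))


def micro_pr_auc(
    prob_matrix: np.ndarray,
    label_sets: Sequence[Iterable[str]],
    groups: Sequence[str],
) -> float:
    """Micro-averaged PR-AUC pooling all (example, group) decisions."""
    labels = np.array(
        [[1 if g in set(ls) else 0 for g in groups] for ls in label_sets]
    )
    return pr_auc(np.asarray(prob_matrix).ravel(), labels.ravel())
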