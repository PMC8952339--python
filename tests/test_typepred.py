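"""Context featurization, multi-label training, thresholds, PR-AUC, oracles."""

import random

import numpy as np
import pytest

import medlink as ml
from medlink.errors import (
    DegenerateTrainingError,
    OracleUnavailableError,
    UndefinedMetricError,
    UnknownGroupError,
)
from medlink.typepred import (
    MEN_CLOSE,
    MEN_OPEN,
    ContextExample,
    examples_from_corpus,
    micro_pr_auc,
    pr_auc,
)


def _doc_and_mention(text, surface, gold_groups=None):
    title, abstract = text.split(" ", 1)
    doc = ml.Document(doc_id="d", title=title, abstract=abstract)
    start = doc.text.index(surface)
    m = ml.Mention(
        doc_id="d",
        start=start,
        end=start + len(surface),
        surface=surface,
        gold_groups=gold_groups,
    )
    return doc, m


class TestFeaturize:
    def test_window_schema(self):
        doc, m = _doc_and_mention("a bad cough and cold today", "cold")
        ex = ml.featurize_context(doc, m, k=2)
        assert ex.tokens == ("cough", "and", MEN_OPEN, "cold", MEN_CLOSE, "today")

    def test_document_start_truncates_left(self):
        doc, m = _doc_and_mention("cold weather is here", "cold")
        ex = ml.featurize_context(doc, m, k=2)
        assert ex.tokens == (MEN_OPEN, "cold", MEN_CLOSE, "weather", "is")

    def test_k_zero_is_markers_only(self):
        doc, m = _doc_and_mention("a bad cold today", "cold")
        assert ml.featurize_context(doc, m, k=0).tokens == (MEN_OPEN, "cold", MEN_CLOSE)

    def test_punctuation_stripped_at_edges(self):
        doc, m = _doc_and_mention("flu, (cough) and cold now.", "cold")
        ex = ml.featurize_context(doc, m, k=3)
        assert ex.tokens[:3] == ("flu", "cough", "and")

    def test_marker_invariants_enforced(self):
        with pytest.raises(Exception):
            ContextExample(tokens=("a", MEN_CLOSE, "b", MEN_OPEN))


class TestTraining:
    def _separable_examples(self, groups, n_per=60, seed=0):
        rng = random.Random(seed)
        cues = {g: f"cue{i}" for i, g in enumerate(groups)}
        examples = []
        for g in groups:
            for _ in range(n_per):
                filler = [f"w{rng.randrange(20)}" for _ in range(2)]
                tokens = (filler[0], cues[g], MEN_OPEN, "thing", MEN_CLOSE, filler[1])
                examples.append(
                    ContextExample(tokens=tokens, label_groups=frozenset({g}), window_k=2)
                )
        rng.shuffle(examples)
        return examples

    def test_separable_data_learned(self, scheme):
        groups = list(scheme.group_names[:3])
        train = self._separable_examples(groups, seed=0)
        held = self._separable_examples(groups, seed=1)
        pred = ml.train_predictor(train, scheme, ml.PredictorConfig(window_k=2, seed=0))
        probs = pred.predict_proba_many(held)
        correct = 0
        for ex, row in zip(held, probs):
            top = pred.groups[int(np.argmax(row))]
            if frozenset({top}) == ex.label_groups:
                correct += 1
        assert correct / len(held) >= 0.95

    def test_same_seed_identical_outputs(self, scheme):
        groups = list(scheme.group_names[:3])
        train = self._separable_examples(groups)
        probe = self._separable_examples(groups, seed=9)[:10]
        cfg = ml.PredictorConfig(window_k=2, seed=7)
        p1 = ml.train_predictor(train, scheme, cfg).predict_proba_many(probe)
        p2 = ml.train_predictor(train, scheme, cfg).predict_proba_many(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_unknown_group_label_raises(self, scheme):
        ex = ContextExample(
            tokens=(MEN_OPEN, "x", MEN_CLOSE), label_groups=frozenset({"Bogus"})
        )
        with pytest.raises(UnknownGroupError):
            ml.train_predictor([ex], scheme)

    def test_all_empty_labels_raise(self, scheme):
        exs = [ContextExample(tokens=(MEN_OPEN, "x", MEN_CLOSE)) for _ in range(5)]
        with pytest.raises(DegenerateTrainingError):
            ml.train_predictor(exs, scheme)

    def test_probabilities_bounded_and_complete(self, trained, test_corpus):
        pred, _ = trained
        examples = [ex for _, ex in examples_from_corpus(test_corpus, 8)][:20]
        for ex in examples:
            proba = pred.predict_proba(ex)
            assert set(proba) == set(pred.groups)
            assert all(0.0 <= v <= 1.0 for v in proba.values())

    def test_identical_examples_identical_vectors(self, trained, test_corpus):
        pred, _ = trained
        ex = next(ex for _, ex in examples_from_corpus(test_corpus, 8))
        assert pred.predict_proba(ex) == pred.predict_proba(ex)

    def test_save_load_roundtrip(self, trained, test_corpus, tmp_path):
        pred, _ = trained
        path = tmp_path / "model.joblib"
        pred.save(path)
        back = ml.TypePredictor.load(path)
        examples = [ex for _, ex in examples_from_corpus(test_corpus, 8)][:5]
        np.testing.assert_array_equal(
            pred.predict_proba_many(examples), back.predict_proba_many(examples)
        )


def _brute_force_best_threshold(scores, labels, grid):
    """Independent exhaustive maximizer: per-threshold F1 by direct counting."""
    best_t, best_f1 = None, -1.0
    for t in grid:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        npred = sum(1 for s in scores if s >= t)
        npos = sum(labels)
        p = tp / npred if npred else 0.0
        r = tp / npos if npos else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t


class TestThresholds:
    class _Stub:
        """Score matrix delivered verbatim, bypassing featurization."""

        def __init__(self, groups, matrix):
            self.groups = tuple(groups)
            self._m = np.asarray(matrix, dtype=float)

        def predict_proba_many(self, examples):
            return self._m

        def predict_proba(self, ex):
            return dict(zip(self.groups, self._m[0].tolist()))

    def test_clean_separation_picks_middle(self):
        labels = [1, 1, 0, 0]
        scores = [[0.9], [0.9], [0.1], [0.1]]
        stub = self._Stub(["G"], scores)
        exs = [
            ContextExample(
                tokens=(MEN_OPEN, "x", MEN_CLOSE),
                label_groups=frozenset({"G"}) if y else frozenset(),
            )
            for y in labels
        ]
        thr = ml.tune_thresholds(stub, exs, grid=[0.05, 0.5, 0.95])
        assert thr["G"] == 0.5

    def test_absent_group_defaults_with_warning(self):
        stub = self._Stub(["G", "H"], [[0.9, 0.2], [0.1, 0.3]])
        exs = [
            ContextExample(tokens=(MEN_OPEN, "x", MEN_CLOSE), label_groups=frozenset({"G"})),
            ContextExample(tokens=(MEN_OPEN, "x", MEN_CLOSE)),
        ]
        with pytest.warns(UserWarning, match="'H'"):
            thr = ml.tune_thresholds(stub, exs)
        assert thr["H"] == 0.5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_grid_search(self, seed):
        rng = random.Random(seed)
        n = 80
        grid = [i / 100 for i in range(1, 100)]
        groups = ["A", "B", "C"]
        matrix = [[rng.random() for _ in groups] for _ in range(n)]
        label_sets = [
            frozenset(g for g in groups if rng.random() < 0.4) for _ in range(n)
        ]
        # ensure every group has a positive
        label_sets[0] = frozenset(groups)
        exs = [
            ContextExample(tokens=(MEN_OPEN, "x", MEN_CLOSE), label_groups=ls)
            for ls in label_sets
        ]
        thr = ml.tune_thresholds(self._Stub(groups, matrix), exs, grid=grid)
        for j, g in enumerate(groups):
            scores = [row[j] for row in matrix]
            labels = [1 if g in ls else 0 for ls in label_sets]
            assert thr[g] == _brute_force_best_threshold(scores, labels, grid)

    def test_predict_groups_thresholding(self):
        stub = self._Stub(["A", "B"], [[0.8, 0.1]])
        ex = ContextExample(tokens=(MEN_OPEN, "x", MEN_CLOSE))
        thr = ml.ThresholdSet({"A": 0.5, "B": 0.5})
        assert ml.predict_groups(stub, thr, ex) == {"A"}
        assert ml.predict_groups(stub, ml.ThresholdSet({"A": 0.9, "B": 0.5}), ex) == frozenset()
        assert ml.predict_groups(stub, ml.ThresholdSet({"A": 0.001, "B": 0.001}), ex) == {"A", "B"}


class TestOracle:
    def test_coarse_maps_fine_types_to_groups(self, scheme, cold_inventory):
        m = ml.Mention(doc_id="d", start=0, end=4, surface="cold", gold_cui="C0009443")
        assert ml.oracle_predict(m, cold_inventory, scheme, "coarse") == {
            "Disease or Syndrome"
        }

    def test_fine_returns_all_gold_types(self, scheme):
        inv = ml.ConceptInventory.from_entries(
            [
                ml.ConceptEntry(
                    cui="C0250873",
                    preferred_name="OX7-SAP",
                    synonyms=(),
                    fine_types=frozenset(
                        {"Pharmacologic Substance", "Immunologic Factor"}
                    ),
                )
            ]
        )
        m = ml.Mention(doc_id="d", start=0, end=7, surface="OX7-SAP", gold_cui="C0250873")
        assert ml.oracle_predict(m, inv, scheme, "fine") == {
            "Pharmacologic Substance",
            "Immunologic Factor",
        }
        assert ml.oracle_predict(m, inv, scheme, "coarse") == {
            "Pharmacologic Substance",
            "Chemicals & Drugs",
        }

    def test_missing_gold_cui_raises(self, scheme, cold_inventory):
        m = ml.Mention(doc_id="d", start=0, end=4, surface="cold")
        with pytest.raises(OracleUnavailableError):
            ml.oracle_predict(m, cold_inventory, scheme, "fine")


def _step_curve_auc(scores, labels):
    """Independent PR step-curve area: sum P_i * (R_i - R_{i-1}) over
    distinct descending score thresholds."""
    order = sorted(set(scores), reverse=True)
    npos = sum(labels)
    auc, prev_r = 0.0, 0.0
    for t in order:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        npred = sum(1 for s in scores if s >= t)
        p = tp / npred
        r = tp / npos
        auc += p * (r - prev_r)
        prev_r = r
    return auc


class TestPRAUC:
    def test_perfect_separation_is_one(self):
        assert ml.pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_equal_positive_rate(self):
        assert ml.pr_auc([0.5] * 10, [1, 0, 0, 0, 1, 0, 0, 0, 0, 0]) == pytest.approx(0.2)

    def test_zero_positives_raise(self):
        with pytest.raises(UndefinedMetricError):
            pr_auc([0.1, 0.2], [0, 0])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_step_curve_oracle(self, seed):
        rng = random.Random(seed)
        n = 50
        scores = [round(rng.random(), 2) for _ in range(n)]  # rounded to force ties
        labels = [rng.randint(0, 1) for _ in range(n)]
        if sum(labels) == 0:
            labels[0] = 1
        assert ml.pr_auc(scores, labels) == pytest.approx(
            _step_curve_auc(scores, labels), abs=1e-12
        )

    def test_micro_variant_pools_pairs(self):
        probs = np.array([[0.9, 0.1], [0.2, 0.8]])
        labels = [{"A"}, {"B"}]
        assert micro_pr_auc(probs, labels, ["A", "B"]) == pytest.approx(
            _step_curve_auc([0.9, 0.1, 0.2, 0.8], [1, 0, 0, 1])
        )
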