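import pytest

import medlink as ml
from medlink.synth import make_candidates


@pytest.fixture(scope="session")
def scheme():
    return ml.load_scheme()


@pytest.fixture(scope="session")
def cold_inventory():
    """The ambiguous-"cold" scenario: one string, three concepts, three groups."""
    return ml.ConceptInventory.from_entries(
        [
            ml.ConceptEntry(
                cui="C0009443",
                preferred_name="Common Cold",
                synonyms=("cold", "acute coryza"),
                fine_types=frozenset({"Disease or Syndrome"}),
            ),
            ml.ConceptEntry(
                cui="C0009264",
                preferred_name="Cold Temperature",
                synonyms=("cold",),
                fine_types=frozenset({"Natural Phenomenon or Process"}),
            ),
            ml.ConceptEntry(
                cui="C0719425",
                preferred_name="Cold Brand",
                synonyms=("cold",),
                fine_types=frozenset({"Pharmacologic Substance"}),
            ),
        ]
    )


@pytest.fixture(scope="session")
def synth_cfg():
    """Default study conditions: separable cues, half the surfaces ambiguous."""
    return ml.SynthConfig(seed=11)


@pytest.fixture(scope="session")
def synth_inventory(synth_cfg, scheme):
    return ml.make_inventory(synth_cfg, scheme)


@pytest.fixture(scope="session")
def synth_corpus(synth_inventory, synth_cfg, scheme):
    return ml.make_corpus(synth_inventory, synth_cfg, scheme)


@pytest.fixture(scope="session")
def trained(scheme, synth_inventory, synth_cfg):
    """Predictor + thresholds trained/tuned on independent synthetic corpora."""
    train_c = ml.make_corpus(synth_inventory, synth_cfg, scheme)
    val_c = ml.make_corpus(
        synth_inventory, ml.SynthConfig(seed=synth_cfg.seed + 1), scheme
    )
    config = ml.PredictorConfig(window_k=8, seed=0)
    from medlink.typepred import examples_from_corpus

    train = [ex for _, ex in examples_from_corpus(train_c, config.window_k)]
    val = [ex for _, ex in examples_from_corpus(val_c, config.window_k)]
    pred = ml.train_predictor(train, scheme, config)
    with pytest.warns(UserWarning):  # groups absent from validation default to 0.5
        thr = ml.tune_thresholds(pred, val)
    return pred, thr


@pytest.fixture(scope="session")
def test_corpus(synth_inventory, synth_cfg, scheme):
    """Held-out corpus drawn with a different seed from the same inventory."""
    return ml.make_corpus(
        synth_inventory, ml.SynthConfig(seed=synth_cfg.seed + 2), scheme
    )


@pytest.fixture(scope="session")
def test_candidates(test_corpus, synth_inventory, synth_cfg):
    return make_candidates(test_corpus, synth_inventory, synth_cfg)
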