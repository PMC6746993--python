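"""Architecture construction, output normalization, save/load contracts."""

import numpy as np
import pytest

from rippnet.encoding import CANONICAL_AMINO_ACIDS, encode
from rippnet.models import (
    ARCHITECTURES,
    Classifier,
    ConfigurationError,
    ModelLoadError,
    ModelSpec,
    build_model,
    load_model,
    save_model,
)


def random_batch(n, seed=0):
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list(CANONICAL_AMINO_ACIDS), size=rng.integers(20, 121)))
            for _ in range(n)]
    return np.stack([encode(s).matrix for s in seqs])


def test_unknown_architecture_rejected():
    with pytest.raises(ConfigurationError, match="unknown architecture"):
        ModelSpec(architecture="transformer")


def test_invalid_fractions_rejected():
    with pytest.raises(ConfigurationError):
        ModelSpec(head_dropout=1.0)


def test_dense_units_resolved_per_trunk():
    assert ModelSpec(architecture="lstm").dense_units == 60
    assert ModelSpec(architecture="cnn_linear").dense_units == 40
    assert ModelSpec(architecture="cnn_linear_lstm").dense_units == 40
    assert ModelSpec(architecture="cnn_parallel").dense_units == 60
    assert ModelSpec(architecture="cnn_parallel_lstm").dense_units == 60


def test_spec_round_trips_through_dict():
    spec = ModelSpec(architecture="cnn_parallel", parallel_branch_filters=32)
    assert ModelSpec.from_dict(spec.to_dict()) == spec


@pytest.mark.parametrize("arch", ARCHITECTURES)
def test_outputs_normalized_and_deterministic(arch):
    model = build_model(arch, seed=3)
    batch = random_batch(6, seed=1)
    p1 = model.predict_proba(batch)
    p2 = model.predict_proba(batch)
    assert p1.shape == (6, 2)
    assert np.all(p1 >= 0)
    np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_array_equal(p1, p2)  # dropout off at inference


@pytest.mark.parametrize("arch", ARCHITECTURES)
def test_same_seed_same_initialization(arch):
    batch = random_batch(3, seed=2)
    p1 = build_model(arch, seed=7).predict_proba(batch)
    p2 = build_model(arch, seed=7).predict_proba(batch)
    p3 = build_model(arch, seed=8).predict_proba(batch)
    np.testing.assert_array_equal(p1, p2)
    assert not np.array_equal(p1, p3)


def test_prediction_is_batching_invariant():
    model = build_model("cnn_parallel", seed=0)
    batch = random_batch(10, seed=3)
    whole = model.predict_proba(batch)
    halves = np.concatenate([model.predict_proba(batch[:5]), model.predict_proba(batch[5:])])
    np.testing.assert_allclose(whole, halves, atol=1e-12)


def test_wrong_input_shape_rejected():
    model = build_model("lstm", seed=0)
    with pytest.raises(ValueError, match="shape"):
        model.predict_proba(np.zeros((2, 20, 60)))


# counts recorded from the first instantiation of each default spec
EXPECTED_PARAM_COUNTS = {
    "lstm": 46_262,
    "cnn_linear": 228_474,
    "cnn_parallel": 363_884,
    "cnn_linear_lstm": 107_274,
    "cnn_parallel_lstm": 238_124,
}


@pytest.mark.parametrize("arch", ARCHITECTURES)
def test_parameter_counts_are_stable(arch):
    assert build_model(arch, seed=0).n_parameters() == EXPECTED_PARAM_COUNTS[arch]


class TestSaveLoad:
    def test_round_trip_reproduces_scores(self, tmp_path):
        model = build_model("cnn_parallel", seed=5)
        batch = random_batch(4, seed=4)
        before = model.predict_proba(batch)
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        np.testing.assert_allclose(loaded.predict_proba(batch), before, atol=1e-6)
        assert loaded.alphabet.symbols == model.alphabet.symbols

    def test_missing_alphabet_field_named(self, tmp_path):
        import json

        model = build_model("lstm", seed=0)
        save_model(model, tmp_path / "m")
        meta_path = tmp_path / "m" / "model.json"
        meta = json.loads(meta_path.read_text())
        del meta["alphabet"]
        meta_path.write_text(json.dumps(meta))
        with pytest.raises(ModelLoadError, match="alphabet"):
            load_model(tmp_path / "m")

    def test_architecture_mismatch_rejected(self, tmp_path):
        model = build_model("cnn_parallel", seed=0)
        save_model(model, tmp_path / "m")
        assert load_model(tmp_path / "m", expected_architecture="cnn_parallel")
        for other in ARCHITECTURES:
            if other == "cnn_parallel":
                continue
            with pytest.raises(ModelLoadError):
                load_model(tmp_path / "m", expected_architecture=other)

    def test_missing_metadata_file(self, tmp_path):
        with pytest.raises(ModelLoadError, match="metadata"):
            load_model(tmp_path)
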