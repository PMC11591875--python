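"""Tests for class weighting, the weighted loss, and the CRNN estimator.

Network-level tests run a deliberately tiny configuration (2 conv blocks,
16 Mel bands, short sequences) so the full train/checkpoint/save-load
machinery is exercised in seconds; the full-width architecture anchors are
covered by the acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from coughkit.crnn import (CheckpointTriple, ClassWeight, CRNNClassifier,
                           CRNNConfig, build_model, class_weight, predict,
                           train, weighted_loss)

TINY = dict(base_filters=4, n_conv_blocks=2, lstm_layers=1, lstm_hidden=8,
            n_mels=16, n_frames=6, batch_size=8)


def _tiny_config(**kw):
    params = dict(TINY, lstm_input=8, epochs=2, seed=0)
    params.update(kw)
    return CRNNConfig(**params)


def _toy_data(n=48, seed=0):
    """Separable toy Mel grids: positives are 'loud' (near 0 dB) up top."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 3 == 0              # ~33% positive
    X = np.full((n, 16, 6), -70.0) + rng.uniform(0, 5, (n, 16, 6))
    X[y, :8, :] = -5.0 + rng.uniform(0, 5, (int(y.sum()), 8, 6))
    return X, y


# ---------------------------------------------------------------------------
# class weight
# ---------------------------------------------------------------------------

def test_class_weight_balanced():
    assert class_weight(10, 10).w_true == 1.0


def test_class_weight_reference_regime():
    cw = class_weight(74, 926)
    assert cw.w_true == pytest.approx(926 / 74)
    assert cw.w_true == pytest.approx(12.514, abs=1e-3)
    assert cw.w_true > 1.0                 # up-weights the minority class


def test_class_weight_monotone_in_n_true():
    weights = [class_weight(n, 500).w_true for n in (10, 50, 100, 499)]
    assert all(b < a for a, b in zip(weights, weights[1:]))


def test_class_weight_requires_both_classes():
    with pytest.raises(ValueError):
        class_weight(0, 10)
    with pytest.raises(ValueError):
        class_weight(10, 0)


# ---------------------------------------------------------------------------
# weighted loss
# ---------------------------------------------------------------------------

def test_loss_positive_at_half_is_ln2():
    assert weighted_loss([1.0], [0.5], 1.0) == pytest.approx(np.log(2))


def test_loss_negative_term_ignores_weight():
    for w in (1.0, 5.0, 12.514):
        assert weighted_loss([0.0], [0.5], w) == pytest.approx(np.log(2))


def test_loss_weighted_positive_example():
    w = 926 / 74
    assert weighted_loss([1.0], [0.5], w) == pytest.approx(w * np.log(2))
    assert weighted_loss([1.0], [0.5], w) == pytest.approx(8.674, abs=2e-3)


@given(st.integers(min_value=1, max_value=50), st.integers(min_value=0))
def test_loss_reduces_to_bce_at_weight_one(n, seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n).astype(float)
    p = rng.uniform(0.01, 0.99, n)
    bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    assert abs(weighted_loss(y, p, 1.0) - bce) < 1e-12


def test_loss_minimized_at_p_equals_y():
    grid = np.linspace(0.01, 0.99, 99)
    for y in (0.0, 1.0):
        losses = [weighted_loss([y], [p], 3.0) for p in grid]
        best = grid[int(np.argmin(losses))]
        assert best == pytest.approx(y, abs=0.011)


def test_loss_clamps_extreme_probabilities():
    assert np.isfinite(weighted_loss([1.0], [0.0], 5.0))
    assert np.isfinite(weighted_loss([0.0], [1.0], 5.0))


# ---------------------------------------------------------------------------
# config and model construction
# ---------------------------------------------------------------------------

def test_config_lstm_input_invariant():
    with pytest.raises(ValueError):
        CRNNConfig(base_filters=4, n_conv_blocks=2, lstm_input=9,
                   n_mels=16, n_frames=6)


def test_config_n_mels_divisibility():
    with pytest.raises(ValueError):
        _tiny_config(n_mels=18, lstm_input=8)


def test_config_head_choices():
    with pytest.raises(ValueError):
        _tiny_config(head="median")


def test_default_config_is_reference_scale():
    cfg = CRNNConfig()
    assert cfg.base_filters == 128
    assert cfg.lstm_input == 1024
    assert cfg.lstm_hidden == 512
    assert cfg.lstm_layers == 4
    assert cfg.epochs == 50


def test_model_channel_doubling_and_sequence_shape():
    model = build_model(_tiny_config())
    outs = [b.conv1.weight.shape[0] for b in model.blocks]
    assert outs == [4, 8]
    proba = model.predict_proba(np.zeros((3, 16, 6)))
    assert proba.shape == (3,)
    assert np.all((proba > 0) & (proba < 1))


def test_forward_rejects_wrong_shape():
    model = build_model(_tiny_config())
    with pytest.raises(ValueError):
        model.forward(np.zeros((2, 16, 7)))


def test_mean_head_runs():
    model = build_model(_tiny_config(head="mean"))
    p = model.predict_proba(np.zeros((2, 16, 6)))
    assert np.all((p > 0) & (p < 1))


# ---------------------------------------------------------------------------
# training machinery
# ---------------------------------------------------------------------------

def test_checkpoint_triple_tracks_maxima():
    triple = CheckpointTriple()
    triple.update(0, {"accuracy": 0.5, "sensitivity": 0.9, "mixed": 1.4}, {})
    triple.update(1, {"accuracy": 0.8, "sensitivity": 0.2, "mixed": 1.0}, {})
    triple.update(2, {"accuracy": 0.6, "sensitivity": 0.6, "mixed": 1.2}, {})
    assert triple.best_accuracy.epoch == 1
    assert triple.best_sensitivity.epoch == 0
    assert triple.best_mixed.epoch == 0


def test_checkpoint_triple_ignores_absent_metrics():
    triple = CheckpointTriple()
    triple.update(0, {"accuracy": 0.5, "sensitivity": None, "mixed": None}, {})
    assert triple.best_accuracy is not None
    assert triple.best_sensitivity is None


def test_train_history_and_checkpoints():
    X, y = _toy_data()
    cfg = _tiny_config(epochs=3)
    model = build_model(cfg)
    triple, history = train(model, (X[:36], y[:36]), (X[36:], y[36:]), cfg)
    assert isinstance(history, pd.DataFrame)
    assert len(history) == 3 * 2           # one row per (epoch, split)
    assert set(history["split"]) == {"train", "test"}
    assert {"loss", "accuracy", "sensitivity",
            "specificity"} <= set(history.columns)
    # best_mixed dominates every recorded test epoch
    test_rows = history[history["split"] == "test"]
    mixed = (test_rows["accuracy"] + test_rows["sensitivity"]).max()
    assert triple.best_mixed.metrics["mixed"] == pytest.approx(mixed)


def test_train_rejects_single_class():
    X, y = _toy_data()
    cfg = _tiny_config(epochs=1)
    with pytest.raises(ValueError):
        train(build_model(cfg), (X, np.zeros(len(X), bool)), (X, y), cfg)


def test_predict_helper_thresholds():
    X, y = _toy_data(n=12)
    model = build_model(_tiny_config())
    proba, labels = predict(model, X, threshold=0.5)
    assert proba.shape == (12,)
    assert np.array_equal(labels, proba >= 0.5)
    proba2, _ = predict(model, X)
    assert np.array_equal(proba, proba2)   # deterministic


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

def test_classifier_learns_separable_toy_data():
    X, y = _toy_data(n=60)
    clf = CRNNClassifier(epochs=6, seed=0, **TINY).fit(X, y)
    assert clf.classes_.tolist() == [False, True]
    acc = np.mean(clf.predict(X) == y)
    assert acc > 0.9
    proba = clf.predict_proba(X)
    assert proba.shape == (60, 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
    # positives score higher than negatives on average
    s = clf.decision_function(X)
    assert s[y].mean() > s[~y].mean()


def test_classifier_deterministic_given_seed():
    X, y = _toy_data(n=32)
    a = CRNNClassifier(epochs=2, seed=3, **TINY).fit(X, y)
    b = CRNNClassifier(epochs=2, seed=3, **TINY).fit(X, y)
    for pa, pb in zip(a.model_.params, b.model_.params):
        assert np.array_equal(pa.data, pb.data)
    assert a.history_.equals(b.history_)


def test_classifier_rejects_single_class():
    X, _ = _toy_data(n=16)
    with pytest.raises(ValueError):
        CRNNClassifier(epochs=1, **TINY).fit(X, np.ones(16, bool))


def test_classifier_sklearn_params_roundtrip():
    clf = CRNNClassifier(epochs=2, seed=5, **TINY)
    params = clf.get_params()
    clone = CRNNClassifier(**params)
    assert clone.get_params() == params


def test_classifier_save_load_roundtrip(tmp_path):
    X, y = _toy_data(n=32)
    clf = CRNNClassifier(epochs=2, seed=1, **TINY).fit(X, y)
    path = tmp_path / "ckpt.npz"
    clf.save(path)
    loaded = CRNNClassifier.load(path)
    np.testing.assert_allclose(loaded.decision_function(X),
                               clf.decision_function(X), atol=1e-6)


def test_classifier_weighted_flag_changes_class_weight():
    X, y = _toy_data(n=32)
    clf_w = CRNNClassifier(epochs=1, seed=0, weighted=True, **TINY).fit(X, y)
    clf_u = CRNNClassifier(epochs=1, seed=0, weighted=False, **TINY).fit(X, y)
    assert clf_w.class_weight_ is not None
    assert clf_w.class_weight_.w_true > 1.0
    assert clf_u.class_weight_ is None
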