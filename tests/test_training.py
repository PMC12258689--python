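"""Loss terms, metrics, oversampling, seeded training, localization AUC."""

import numpy as np
import pytest

from scamnet import (
    ModelConfig,
    compute_loss,
    evaluate,
    generate_dataset,
    localization_auc,
    metrics_from_confusion,
    train,
)
from scamnet.model import ExplanationMask, Prediction
from scamnet.training import _oversampled_indices


def make_pred(probs, node_imp, edge_imp):
    probs = np.asarray(probs, dtype=float)
    return Prediction(
        probabilities=probs,
        predicted_class=int(np.argmax(probs)),
        mask=ExplanationMask(
            node_importances=np.asarray(node_imp, dtype=float),
            edge_importances=np.asarray(edge_imp, dtype=float),
        ),
        graph_embedding=np.zeros(4),
    )


def test_loss_zero_for_confident_correct_sparse():
    pred = make_pred([1.0, 0.0], np.zeros((5, 2)), np.zeros((8, 2)))
    out = compute_loss(pred, 0, ModelConfig())
    assert out.classification == pytest.approx(0.0, abs=1e-9)
    assert out.sparsity == pytest.approx(0.0)


def test_loss_uniform_probabilities_is_ln2():
    pred = make_pred([0.5, 0.5], np.zeros((3, 2)), np.zeros((4, 2)))
    out = compute_loss(pred, 1, ModelConfig())
    assert out.classification == pytest.approx(np.log(2), abs=1e-9)


def test_sparsity_term_all_ones_node_mask():
    # 10-node graph with no edges: mean importance is exactly 1
    pred = make_pred([0.9, 0.1], np.ones((10, 2)), np.zeros((0, 2)))
    out = compute_loss(pred, 0, ModelConfig(sparsity_weight=1.0))
    assert out.sparsity == pytest.approx(1.0)


def test_loss_breakdown_additivity_random_cases():
    rng = np.random.default_rng(0)
    cfg = ModelConfig(sparsity_weight=0.3, cotrain_weight=0.7)
    for _ in range(1000):
        p1 = rng.uniform(0.001, 0.999)
        n, e = rng.integers(1, 12), rng.integers(0, 20)
        pred = make_pred(
            [1 - p1, p1], rng.uniform(0, 1, (n, 2)), rng.uniform(0, 1, (e, 2))
        )
        out = compute_loss(pred, int(rng.integers(2)), cfg)
        recomputed = (
            out.classification
            + cfg.cotrain_weight * out.cotraining
            + cfg.sparsity_weight * out.sparsity
        )
        assert out.total == pytest.approx(recomputed, abs=1e-6)
        assert np.isfinite([out.total, out.classification, out.cotraining, out.sparsity]).all()


def test_loss_rejects_non_binary_label():
    pred = make_pred([0.5, 0.5], np.zeros((2, 2)), np.zeros((0, 2)))
    with pytest.raises(ValueError):
        compute_loss(pred, 2, ModelConfig())


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------


def test_external_validation_worked_example():
    m = metrics_from_confusion(tp=15, fn=15, tn=24, fp=4)
    assert m.accuracy == pytest.approx(39 / 58)
    assert m.balanced_accuracy == pytest.approx(0.5 * (0.5 + 24 / 28))
    assert round(m.balanced_accuracy * 100) == 68


def test_comparison_model_worked_example():
    m = metrics_from_confusion(tp=2, fn=28, tn=27, fp=1)
    assert m.accuracy == pytest.approx(0.5)


def test_perfect_confusion_metrics():
    m = metrics_from_confusion(tp=10, fn=0, tn=10, fp=0)
    assert m.accuracy == m.balanced_accuracy == m.f1 == 1.0


def test_all_negative_predictions_on_balanced_set():
    m = metrics_from_confusion(tp=0, fn=10, tn=10, fp=0)
    assert m.accuracy == pytest.approx(0.5)
    assert m.f1 == pytest.approx(0.0)


def test_confusion_margin_errors():
    with pytest.raises(ValueError):
        metrics_from_confusion(0, 0, 5, 5)
    with pytest.raises(ValueError):
        metrics_from_confusion(5, 5, 0, 0)
    with pytest.raises(ValueError):
        metrics_from_confusion(-1, 5, 5, 5)


# --------------------------------------------------------------------------
# Oversampling + training loop
# --------------------------------------------------------------------------


def test_oversampling_reaches_parity():
    rng = np.random.default_rng(0)
    labels = np.array([1] * 10 + [0] * 140)
    idx = _oversampled_indices(labels, rng)
    sampled = labels[idx]
    assert (sampled == 1).sum() == (sampled == 0).sum() == 140
    # every minority record appears
    assert set(idx[sampled == 1]) == set(range(10))


def test_oversampling_balanced_input_untouched():
    rng = np.random.default_rng(0)
    labels = np.array([0, 1] * 20)
    idx = _oversampled_indices(labels, rng)
    assert len(idx) == 40 and sorted(idx) == list(range(40))


@pytest.fixture(scope="module")
def tiny_run(spec, small_config):
    ds = generate_dataset(240, 0.5, seed=42)
    train_rec, test_rec = ds.records[:180], ds.records[180:]
    params, history = train(train_rec, small_config, spec, seed=1, epochs=8)
    return ds, train_rec, test_rec, params, history


def test_training_loss_decreases(tiny_run):
    _, _, _, _, history = tiny_run
    assert history.epochs[-1].total < history.epochs[0].total
    assert len(history.epochs) == 8


def test_training_deterministic_first_epoch(tiny_run, spec, small_config):
    _, train_rec, _, _, history = tiny_run
    _, hist2 = train(train_rec, small_config, spec, seed=1, epochs=1)
    assert abs(hist2.epochs[0].total - history.epochs[0].total) < 1e-6


def test_evaluate_agrees_with_confusion(tiny_run):
    _, _, test_rec, params, _ = tiny_run
    from scamnet.training import _predict_labels

    m = evaluate(params, test_rec)
    preds = _predict_labels(params, test_rec)
    labels = np.array([r.label for r in test_rec])
    tp = int(((preds == 1) & (labels == 1)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    assert m == metrics_from_confusion(tp, fn, tn, fp)
    assert m.tp + m.fn + m.tn + m.fp == len(test_rec)


def test_single_class_dataset_rejected(spec, small_config):
    ds = generate_dataset(20, 0.5, seed=0)
    only_pos = [r for r in ds.records if r.label == 1]
    with pytest.raises(ValueError):
        train(only_pos, small_config, spec, seed=0, epochs=1)


# --------------------------------------------------------------------------
# Localization AUC
# --------------------------------------------------------------------------


def brute_force_auc(scores, y):
    """Quadratic pairwise-comparison AUC oracle (ties count half)."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_localization_auc_perfect_and_uninformative():
    mask = {1, 3}
    assert localization_auc(np.array([0, 1, 0, 1, 0.0]), mask, 5) == 1.0
    assert localization_auc(np.full(5, 0.7), mask, 5) == 0.5


def test_localization_auc_matches_pairwise_oracle():
    rng = np.random.default_rng(8)
    for _ in range(20):
        n = int(rng.integers(4, 15))
        mask = set(rng.choice(n, size=int(rng.integers(1, n - 1)), replace=False).tolist())
        scores = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
        y = np.array([1 if i in mask else 0 for i in range(n)])
        assert localization_auc(scores, mask, n) == pytest.approx(
            brute_force_auc(scores, y)
        )


def test_explanation_localization_on_trained_model(tiny_run):
    from scamnet import SyntheticDataset, explanation_localization

    ds, _, test_rec, params, _ = tiny_run
    sub = SyntheticDataset(
        records=ds.records[180:],
        truth_masks=ds.truth_masks[180:],
        seed=ds.seed,
        rules=ds.rules,
    )
    auc = explanation_localization(params, sub)
    assert 0.0 <= auc <= 1.0


def test_explanation_localization_requires_aggregators(tiny_run, spec):
    from scamnet import SyntheticDataset, explanation_localization

    ds, _, _, params, _ = tiny_run
    neg_only = [r for r in ds.records if r.label == 0]
    sub = SyntheticDataset(
        records=neg_only,
        truth_masks=[frozenset()] * len(neg_only),
        seed=0,
        rules=ds.rules,
    )
    with pytest.raises(ValueError):
        explanation_localization(params, sub)
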