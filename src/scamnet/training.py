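"""Loss construction, imbalance-aware training loop, and evaluation metrics.

The loss has three parts: cross-entropy on the class probabilities,
an explanation co-training term (cross-entropy of an auxiliary class
estimate computed from per-channel node-importance totals alone, which ties
channel k to class k), and an L1 sparsity term on the importance masks.
Class imbalance is handled by oversampling the minority class to parity
within each epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .autodiff import Adam, Tensor, concat
from .chemio import FeatureSpec, LabeledRecord, to_graph
from .model import (
    ModelConfig,
    ModelParameters,
    Prediction,
    forward_batch,
    init_params,
    make_batch,
)

__all__ = [
    "LossBreakdown",
    "Metrics",
    "TrainHistory",
    "EpochRecord",
    "compute_loss",
    "train",
    "evaluate",
    "metrics_from_confusion",
    "localization_auc",
    "explanation_localization",
]


@dataclass(frozen=True)
class LossBreakdown:
    """total = classification + beta * co-training + gamma * sparsity."""

    total: float
    classification: float
    cotraining: float
    sparsity: float


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


def compute_loss(pred: Prediction, label: int, config: ModelConfig) -> LossBreakdown:
    """Loss terms for a single prediction.

    Classification: cross-entropy of the class probabilities. Co-training:
    cross-entropy of softmax over per-channel summed node importances —
    the mask magnitudes alone must point at the true class. Sparsity: mean
    of all node and edge importance entries (they are nonnegative, so this
    is their mean absolute value).
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    eps = 1e-12
    classification = float(-np.log(pred.probabilities[label] + eps))
    imp_sums = pred.mask.node_importances.sum(axis=0)
    aux = _softmax(imp_sums)
    cotraining = float(-np.log(aux[label] + eps))
    entries = np.concatenate(
        [pred.mask.node_importances.ravel(), pred.mask.edge_importances.ravel()]
    )
    sparsity = float(entries.mean()) if entries.size else 0.0
    total = (
        classification
        + config.cotrain_weight * cotraining
        + config.sparsity_weight * sparsity
    )
    return LossBreakdown(
        total=total, classification=classification, cotraining=cotraining, sparsity=sparsity
    )


def _batch_loss(out: dict, labels: np.ndarray, config: ModelConfig) -> tuple[Tensor, dict]:
    """Differentiable batch loss mirroring compute_loss, averaged over graphs."""
    B = labels.shape[0]
    onehot = np.zeros((B, config.num_channels))
    onehot[np.arange(B), labels] = 1.0
    Y = Tensor(onehot)
    eps = 1e-12

    p_true = (out["probs"] * Y).sum(axis=1, keepdims=True)
    cls = -((p_true + eps).log()).mean()

    m = out["aux_logits"].data.max(axis=1, keepdims=True)
    z = (out["aux_logits"] - Tensor(m)).exp()
    aux_p = z / z.sum(axis=1, keepdims=True)
    aux_true = (aux_p * Y).sum(axis=1, keepdims=True)
    co = -((aux_true + eps).log()).mean()

    n_entries = out["node_imp"].data.size + out["edge_imp"].data.size
    sparsity = (out["node_imp"].sum() + out["edge_imp"].sum()) * (1.0 / n_entries)

    total = cls + config.cotrain_weight * co + config.sparsity_weight * sparsity
    terms = {
        "classification": float(cls.data),
        "cotraining": float(co.data),
        "sparsity": float(sparsity.data),
        "total": float(total.data),
    }
    return total, terms


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Metrics:
    """Confusion counts and derived scores; positive class = aggregator (1)."""

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    balanced_accuracy: float
    f1: float


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> Metrics:
    """Accuracy, balanced accuracy (mean of per-class recalls), and F1."""
    for v in (tp, fn, tn, fp):
        if v < 0:
            raise ValueError("confusion counts must be nonnegative")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("each true class must have at least one example")
    total = tp + fn + tn + fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return Metrics(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        accuracy=(tp + tn) / total,
        balanced_accuracy=0.5 * (sens + spec),
        f1=f1,
    )


_EVAL_BATCH = 256


def _predict_labels(params: ModelParameters, records: list[LabeledRecord]) -> np.ndarray:
    graphs = [to_graph(r.molecule, params.spec) for r in records]
    preds = np.zeros(len(records), dtype=np.int64)
    for start in range(0, len(graphs), _EVAL_BATCH):
        chunk = graphs[start : start + _EVAL_BATCH]
        out = forward_batch(params, make_batch(chunk))
        preds[start : start + len(chunk)] = np.argmax(out["probs"].data, axis=1)
    return preds


def evaluate(params: ModelParameters, records: list[LabeledRecord]) -> Metrics:
    """Metrics from argmax predictions against labels."""
    if not records:
        raise ValueError("records must be non-empty")
    preds = _predict_labels(params, records)
    labels = np.array([r.label for r in records])
    tp = int(np.sum((preds == 1) & (labels == 1)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    return metrics_from_confusion(tp, fn, tn, fp)


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------


@dataclass
class EpochRecord:
    epoch: int
    total: float
    classification: float
    cotraining: float
    sparsity: float
    metrics: Metrics | None = None


@dataclass
class TrainHistory:
    epochs: list[EpochRecord] = field(default_factory=list)
    seed: int = 0
    config: ModelConfig | None = None


def _oversampled_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """All majority indices plus the minority repeated/resampled to parity."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    if len(minority) == len(majority):
        idx = np.concatenate([majority, minority])
    else:
        reps = len(majority) // len(minority)
        extra = len(majority) - reps * len(minority)
        resampled = np.concatenate(
            [np.tile(minority, reps), rng.choice(minority, size=extra, replace=False)]
        )
        idx = np.concatenate([majority, resampled])
    rng.shuffle(idx)
    return idx


def train(
    records: list[LabeledRecord],
    config: ModelConfig,
    spec: FeatureSpec,
    seed: int,
    epochs: int,
    val_records: list[LabeledRecord] | None = None,
) -> tuple[ModelParameters, TrainHistory]:
    """Seeded training with per-epoch minority oversampling to parity.

    Per-epoch validation metrics are computed on ``val_records`` when given,
    otherwise on the training records. Same seed + same data reproduce the
    history within floating tolerance.
    """
    labels = np.array([r.label for r in records])
    if len(records) < 2 or len(np.unique(labels)) < 2:
        raise ValueError("training requires at least two records with both classes present")
    graphs = [to_graph(r.molecule, spec) for r in records]
    params = init_params(config, spec, seed)
    opt = Adam(params.tensors(), lr=config.learning_rate)
    rng = np.random.default_rng(seed)
    history = TrainHistory(seed=seed, config=config)

    for epoch in range(epochs):
        idx = _oversampled_indices(labels, rng)
        sums = {"total": 0.0, "classification": 0.0, "cotraining": 0.0, "sparsity": 0.0}
        n_batches = 0
        for start in range(0, len(idx), config.batch_size):
            sel = idx[start : start + config.batch_size]
            batch = make_batch([graphs[i] for i in sel])
            out = forward_batch(params, batch)
            loss, terms = _batch_loss(out, labels[sel], config)
            opt.zero_grad()
            loss.backward()
            opt.step()
            for key in sums:
                sums[key] += terms[key]
            n_batches += 1
        metrics = evaluate(params, val_records if val_records is not None else records)
        history.epochs.append(
            EpochRecord(
                epoch=epoch,
                total=sums["total"] / n_batches,
                classification=sums["classification"] / n_batches,
                cotraining=sums["cotraining"] / n_batches,
                sparsity=sums["sparsity"] / n_batches,
                metrics=metrics,
            )
        )
    return params, history


# --------------------------------------------------------------------------
# Explanation localization
# --------------------------------------------------------------------------


def localization_auc(importances: np.ndarray, truth_atoms, num_atoms: int) -> float:
    """ROC AUC of per-atom importances as a ranker of truth-mask membership."""
    y = np.zeros(num_atoms)
    y[sorted(truth_atoms)] = 1.0
    return float(roc_auc_score(y, importances))


def explanation_localization(params: ModelParameters, dataset) -> float:
    """AUC of channel-1 node importances as a ranker of planted-motif atoms.

    Averaged over aggregator-labeled records; records whose truth mask covers
    no atoms or every atom carry no ranking information and are skipped.
    """
    aucs = []
    n_agg = 0
    for rec, mask in zip(dataset.records, dataset.truth_masks):
        if rec.label != 1:
            continue
        n_agg += 1
        n = rec.molecule.num_atoms
        if not mask or len(mask) >= n:
            continue
        graph = to_graph(rec.molecule, params.spec)
        out = forward_batch(params, make_batch([graph]))
        aucs.append(localization_auc(out["node_imp"].data[:, 1], mask, n))
    if n_agg == 0:
        raise ValueError("dataset contains no aggregator records")
    return float(np.mean(aucs)) if aucs else 0.5
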