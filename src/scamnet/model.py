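"""Multi-channel attention message-passing classifier with built-in explanations.

The model maintains one message-passing stream per output class ("channel"):
channel 1 accumulates structural evidence for the aggregator class, channel 0
for the non-aggregator class. Per layer and channel, an edge attention logit
is computed by a single-layer perceptron over (source embedding, target
embedding, edge features); messages are attention-softmax-weighted sums over
incoming edges; the node update is a ReLU of (self-transformed embedding +
aggregated message).

Explanation masks are derived from the internal attention values: the node
importance of channel k is sigmoid(sum over layers of the node's incident
attention logits) times a learned sigmoid node gate; edge importance is the
sigmoid of the summed per-layer attention logits. Channel k contributes to
the classifier only through its importance-masked pooled node embeddings,
so the masks are the causal path from structure to class evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, gather, segment_softmax, segment_sum
from .chemio import FeatureSpec, FeaturizedGraph

__all__ = [
    "ModelConfig",
    "ModelParameters",
    "ExplanationMask",
    "Prediction",
    "GraphBatch",
    "CheckpointError",
    "init_params",
    "forward",
    "forward_batch",
    "node_channel_embeddings",
    "make_batch",
    "save_checkpoint",
    "load_checkpoint",
]


class CheckpointError(ValueError):
    """Raised on checkpoint/key/shape mismatches."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; one channel per output class (binary: K = 2)."""

    num_channels: int = 2
    num_layers: int = 3
    hidden_dim: int = 64
    final_widths: tuple[int, ...] = (64, 32, 2)
    sparsity_weight: float = 0.01  # gamma: L1 pressure on importance masks
    cotrain_weight: float = 1.0  # beta: explanation/class alignment term
    learning_rate: float = 1e-3
    batch_size: int = 32

    def __post_init__(self):
        if self.num_channels != 2:
            raise ValueError("binary classifier: num_channels must be 2")
        if self.num_layers < 1:
            raise ValueError("need at least one message-passing layer")
        if any(w <= 0 for w in self.final_widths) or self.hidden_dim <= 0:
            raise ValueError("widths must be positive")
        if self.final_widths[-1] != self.num_channels:
            raise ValueError("final layer width must equal the number of classes")
        if self.sparsity_weight < 0 or self.cotrain_weight < 0:
            raise ValueError("loss weights must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "num_channels": self.num_channels,
            "num_layers": self.num_layers,
            "hidden_dim": self.hidden_dim,
            "final_widths": list(self.final_widths),
            "sparsity_weight": self.sparsity_weight,
            "cotrain_weight": self.cotrain_weight,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        d["final_widths"] = tuple(d["final_widths"])
        return ModelConfig(**d)


def _param_shapes(config: ModelConfig, spec: FeatureSpec) -> dict[str, tuple[int, ...]]:
    """Parameter name -> shape; fully determined by (config, spec)."""
    d, e = config.hidden_dim, spec.edge_dim
    shapes: dict[str, tuple[int, ...]] = {
        "embed/W": (spec.node_dim, d),
        "embed/b": (1, d),
    }
    for layer in range(config.num_layers):
        for k in range(config.num_channels):
            p = f"layer{layer}/ch{k}"
            shapes[f"{p}/att_W"] = (2 * d + e, 1)
            shapes[f"{p}/att_b"] = (1, 1)
            shapes[f"{p}/msg_W"] = (d, d)
            shapes[f"{p}/self_W"] = (d, d)
            shapes[f"{p}/self_b"] = (1, d)
    for k in range(config.num_channels):
        shapes[f"ch{k}/gate_W"] = (d, 1)
        shapes[f"ch{k}/gate_b"] = (1, 1)
    width_in = config.num_channels * d
    for i, w in enumerate(config.final_widths):
        shapes[f"final{i}/W"] = (width_in, w)
        shapes[f"final{i}/b"] = (1, w)
        width_in = w
    return shapes


@dataclass
class ModelParameters:
    """All trainable weights, keyed by name, plus the config/spec that fix shapes."""

    config: ModelConfig
    spec: FeatureSpec
    weights: dict[str, Tensor]

    def tensors(self) -> list[Tensor]:
        return list(self.weights.values())


def init_params(config: ModelConfig, spec: FeatureSpec, seed: int) -> ModelParameters:
    """Glorot-uniform matrices, zero biases; deterministic given seed."""
    rng = np.random.default_rng(seed)
    weights: dict[str, Tensor] = {}
    for name, shape in _param_shapes(config, spec).items():
        if name.endswith("/b") or name.endswith("_b"):
            data = np.zeros(shape)
        else:
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            data = rng.uniform(-limit, limit, size=shape)
        weights[name] = Tensor(data, requires_grad=True)
    return ModelParameters(config=config, spec=spec, weights=weights)


# --------------------------------------------------------------------------
# Batching: disjoint union of graphs, with node/edge bookkeeping per graph
# --------------------------------------------------------------------------


@dataclass
class GraphBatch:
    node_features: np.ndarray  # (N, node_dim)
    edge_src: np.ndarray  # (E,)
    edge_tgt: np.ndarray  # (E,)
    edge_features: np.ndarray  # (E, edge_dim)
    node_graph: np.ndarray  # (N,) graph id per node
    num_graphs: int
    node_counts: list[int] = field(default_factory=list)
    edge_counts: list[int] = field(default_factory=list)


def make_batch(graphs: list[FeaturizedGraph]) -> GraphBatch:
    xs, srcs, tgts, efs, gids = [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        xs.append(g.node_features)
        if g.num_edges:
            srcs.append(g.edge_index[:, 0] + offset)
            tgts.append(g.edge_index[:, 1] + offset)
        efs.append(g.edge_features)
        gids.append(np.full(g.num_nodes, gi, dtype=np.int64))
        offset += g.num_nodes
    return GraphBatch(
        node_features=np.concatenate(xs, axis=0),
        edge_src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64),
        edge_tgt=np.concatenate(tgts) if tgts else np.zeros(0, dtype=np.int64),
        edge_features=np.concatenate(efs, axis=0),
        node_graph=np.concatenate(gids),
        num_graphs=len(graphs),
        node_counts=[g.num_nodes for g in graphs],
        edge_counts=[g.num_edges for g in graphs],
    )


def _row_softmax(logits: Tensor) -> Tensor:
    m = logits.data.max(axis=1, keepdims=True)  # constant shift
    z = (logits - Tensor(m)).exp()
    return z / z.sum(axis=1, keepdims=True)


def forward_batch(params: ModelParameters, batch: GraphBatch) -> dict:
    """Differentiable forward pass over a disjoint-union batch.

    Returns Tensors: 'probs' (B,K), 'logits' (B,K), 'aux_logits' (B,K) —
    per-channel summed node importances for explanation co-training,
    'node_imp' (N,K), 'edge_imp' (E,K), 'graph_emb' (B,K*d), and per-channel
    node embeddings 'node_emb' (list of K (N,d) Tensors).
    """
    cfg, spec, W = params.config, params.spec, params.weights
    N = batch.node_features.shape[0]
    B = batch.num_graphs
    if batch.node_features.shape[1] != spec.node_dim:
        raise ValueError(
            f"node feature dim {batch.node_features.shape[1]} != spec dim {spec.node_dim}"
        )
    X = Tensor(batch.node_features)
    Ef = Tensor(batch.edge_features)
    src, tgt = batch.edge_src, batch.edge_tgt

    h0 = X @ W["embed/W"] + W["embed/b"]
    node_imps, edge_imps, graph_embs, imp_sums, node_embs = [], [], [], [], []
    for k in range(cfg.num_channels):
        h = h0
        logit_acc: Tensor | None = None
        for layer in range(cfg.num_layers):
            p = f"layer{layer}/ch{k}"
            hs = gather(h, src)
            ht = gather(h, tgt)
            a = concat([hs, ht, Ef], axis=1) @ W[f"{p}/att_W"] + W[f"{p}/att_b"]
            alpha = segment_softmax(a, tgt, N)
            msg = segment_sum(alpha * (hs @ W[f"{p}/msg_W"]), tgt, N)
            h = (h @ W[f"{p}/self_W"] + msg + W[f"{p}/self_b"]).relu()
            logit_acc = a if logit_acc is None else logit_acc + a
        node_logit = segment_sum(logit_acc, tgt, N) + segment_sum(logit_acc, src, N)
        gate = (h @ W[f"ch{k}/gate_W"] + W[f"ch{k}/gate_b"]).sigmoid()
        node_imp = node_logit.sigmoid() * gate  # (N,1), in [0,1]
        edge_imp = logit_acc.sigmoid()  # (E,1)
        node_imps.append(node_imp)
        edge_imps.append(edge_imp)
        node_embs.append(h)
        graph_embs.append(segment_sum(node_imp * h, batch.node_graph, B))
        imp_sums.append(segment_sum(node_imp, batch.node_graph, B))

    g = concat(graph_embs, axis=1)  # (B, K*d) — masks are the only path in
    graph_emb = g
    for i in range(len(cfg.final_widths)):
        g = g @ W[f"final{i}/W"] + W[f"final{i}/b"]
        if i < len(cfg.final_widths) - 1:
            g = g.relu()
    probs = _row_softmax(g)
    return {
        "logits": g,
        "probs": probs,
        "aux_logits": concat(imp_sums, axis=1),
        "node_imp": concat(node_imps, axis=1),
        "edge_imp": concat(edge_imps, axis=1),
        "graph_emb": graph_emb,
        "node_emb": node_embs,
    }


# --------------------------------------------------------------------------
# Public single-graph surface
# --------------------------------------------------------------------------


@dataclass
class ExplanationMask:
    """Per-node and per-directed-edge importances in [0,1], one column per channel."""

    node_importances: np.ndarray  # (num_nodes, K)
    edge_importances: np.ndarray  # (num_directed_edges, K)


@dataclass
class Prediction:
    probabilities: np.ndarray  # (K,), sums to 1
    predicted_class: int
    mask: ExplanationMask
    graph_embedding: np.ndarray  # (K*d,) pre-logit pooled embedding


def forward(params: ModelParameters, graph: FeaturizedGraph) -> Prediction:
    """Class probabilities plus one explanation mask per class channel."""
    out = forward_batch(params, make_batch([graph]))
    probs = out["probs"].data[0]
    return Prediction(
        probabilities=probs,
        predicted_class=int(np.argmax(probs)),
        mask=ExplanationMask(
            node_importances=out["node_imp"].data.copy(),
            edge_importances=out["edge_imp"].data.copy(),
        ),
        graph_embedding=out["graph_emb"].data[0].copy(),
    )


def node_channel_embeddings(params: ModelParameters, graph: FeaturizedGraph) -> np.ndarray:
    """Final-layer node embeddings per channel, before pooling: (num_nodes, K, d).

    Pooling these with the forward mask reproduces the pre-logit graph
    embedding used for the class logits.
    """
    out = forward_batch(params, make_batch([graph]))
    return np.stack([h.data for h in out["node_emb"]], axis=1)


# --------------------------------------------------------------------------
# Checkpointing
# --------------------------------------------------------------------------


def save_checkpoint(params: ModelParameters, path: str | Path) -> None:
    """Single .npz archive: config + feature spec + named weight arrays."""
    meta = json.dumps(
        {"config": params.config.to_dict(), "spec": params.spec.to_dict()},
        sort_keys=True,
    )
    np.savez(str(path), __meta__=np.array(meta), **{k: t.data for k, t in params.weights.items()})


def load_checkpoint(path: str | Path) -> ModelParameters:
    """Load a checkpoint; fails loudly on missing/extra keys or shape drift."""
    path = Path(path)
    if not path.exists():
        raise CheckpointError(f"checkpoint not found: {path}")
    with np.load(str(path), allow_pickle=False) as npz:
        if "__meta__" not in npz:
            raise CheckpointError("checkpoint missing metadata entry")
        meta = json.loads(str(npz["__meta__"]))
        config = ModelConfig.from_dict(meta["config"])
        spec = FeatureSpec.from_dict(meta["spec"])
        expected = _param_shapes(config, spec)
        stored = {k for k in npz.files if k != "__meta__"}
        missing = sorted(set(expected) - stored)
        extra = sorted(stored - set(expected))
        if missing or extra:
            raise CheckpointError(f"checkpoint key mismatch: missing={missing} extra={extra}")
        weights = {}
        for name, shape in expected.items():
            arr = npz[name]
            if arr.shape != shape:
                raise CheckpointError(f"shape mismatch for {name}: {arr.shape} != {shape}")
            weights[name] = Tensor(arr.copy(), requires_grad=True)
    return ModelParameters(config=config, spec=spec, weights=weights)
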