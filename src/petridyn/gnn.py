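"""Edge-aware graph convolutional network for subgraph classification.

The model stacks L graph-convolutional layers.  At layer l, each node v
aggregates its in-neighbors per edge label a (sum over u with an edge
u -> v labeled a), applies a label-specific trainable matrix E_a^l to
each aggregate, sums the results, adds W^l applied to v's previous
embedding, and passes the result through ReLU followed by batch
normalization:

    h_{A,v}^l = sum_a E_a^l * sum_{u in gamma(v,a)} h_u^{l-1}
    h_v^l     = BN(ReLU(W^l h_v^{l-1} + h_{A,v}^l))

Per-layer mean-pooled graph embeddings are concatenated into a single
vector h_g of length d*L, and the prediction is sigmoid(w.h_g + b),
trained with binary cross-entropy.

Ablation variants change the feature width and the aggregation:

========== ================================ ===========================
variant     node features                    neighbor aggregation
========== ================================ ===========================
baseline    Source, Dest, NodeType (3)       none (h_{A,v} = 0)
connectivity constant 1 (1)                  shared matrix U^l
source_dest Source, Dest (2)                 shared matrix U^l
node_type   Source, Dest, NodeType (3)       shared matrix U^l
edge_aware  Source, Dest, NodeType (3)       per-label matrices E_a^l
========== ================================ ===========================

Everything runs on plain numpy with hand-written backpropagation and an
Adam optimizer; graphs are batched as one block-diagonal sparse
adjacency per edge label.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .graphprep import EDGE_LABELS, IOSubgraph, LabeledExample

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "ModelParams",
    "Prediction",
    "GraphBatch",
    "forward",
    "predict",
    "loss",
    "train",
    "init_params",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("baseline", "connectivity", "source_dest", "node_type", "edge_aware")
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_CLAMP = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "edge_aware"
    d: int = 16
    layers: int = 6
    lr: float = 1e-2
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0
    labels: tuple[str, ...] = EDGE_LABELS

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.d < 1 or self.layers < 1:
            raise ValueError("d and layers must be >= 1")

    @property
    def feature_width(self) -> int:
        return {"connectivity": 1, "source_dest": 2}.get(self.variant, 3)

    @property
    def uses_edges(self) -> bool:
        return self.variant != "baseline"

    @property
    def edge_aware(self) -> bool:
        return self.variant == "edge_aware"


@dataclass
class ModelParams:
    """All trainable tensors plus batch-normalization running statistics.

    ``tensors`` maps names to arrays: ``W{l}`` node matrices,
    ``E:{label}:{l}`` per-label edge matrices (edge-aware variant),
    ``U{l}`` shared-neighbor matrices (other structure-aware variants),
    ``gamma{l}``/``beta{l}`` batch-norm affine parameters, ``w_out`` the
    readout vector (length d*layers) and ``b_out`` the bias.  Running
    batch-norm statistics live in ``running`` (``mean{l}``, ``var{l}``)
    and are not trained.
    """

    tensors: dict[str, np.ndarray]
    running: dict[str, np.ndarray]

    def copy(self) -> "ModelParams":
        return ModelParams(
            {k: v.copy() for k, v in self.tensors.items()},
            {k: v.copy() for k, v in self.running.items()},
        )


@dataclass
class Prediction:
    probability: float
    graph_embedding: np.ndarray  # (d*L,)
    node_embeddings: list[np.ndarray] | None = None  # per layer (n, d)


def init_params(cfg: ModelConfig, rng: np.random.Generator | None = None) -> ModelParams:
    """Glorot-uniform initialization, deterministic given the config seed."""
    rng = rng or np.random.default_rng(cfg.seed)

    def glorot(shape):
        limit = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-limit, limit, size=shape)

    tensors: dict[str, np.ndarray] = {}
    running: dict[str, np.ndarray] = {}
    d_in = cfg.feature_width
    for layer in range(cfg.layers):
        tensors[f"W{layer}"] = glorot((cfg.d, d_in))
        if cfg.edge_aware:
            for a in cfg.labels:
                tensors[f"E:{a}:{layer}"] = glorot((cfg.d, d_in))
        elif cfg.uses_edges:
            tensors[f"U{layer}"] = glorot((cfg.d, d_in))
        tensors[f"gamma{layer}"] = np.ones(cfg.d)
        tensors[f"beta{layer}"] = np.zeros(cfg.d)
        running[f"mean{layer}"] = np.zeros(cfg.d)
        running[f"var{layer}"] = np.ones(cfg.d)
        d_in = cfg.d
    tensors["w_out"] = glorot((cfg.d * cfg.layers, 1))[:, 0]
    tensors["b_out"] = np.zeros(1)
    return ModelParams(tensors, running)


# ---------------------------------------------------------------------------
# Batching


class GraphBatch:
    """A list of subgraphs packed into one block-diagonal graph."""

    def __init__(self, subs: list[IOSubgraph], cfg: ModelConfig):
        sizes = [s.n_nodes for s in subs]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        n = int(offsets[-1])
        self.n_graphs = len(subs)
        self.n_nodes = n
        self.sizes = np.array(sizes)
        self.graph_id = np.repeat(np.arange(len(subs)), sizes)
        feats = []
        for s in subs:
            if s.features is None:
                raise ValueError("subgraph is not featurized")
            if cfg.variant == "connectivity":
                feats.append(np.ones((s.n_nodes, 1)))
            elif cfg.variant == "source_dest":
                feats.append(s.features[:, :2])
            else:
                feats.append(s.features)
        self.X = np.vstack(feats)

        self.adj: dict[str, sp.csr_matrix] = {}
        self.adj_t: dict[str, sp.csr_matrix] = {}
        if cfg.uses_edges:
            per_label: dict[str, tuple[list[int], list[int]]] = {a: ([], []) for a in cfg.labels}
            for s, off in zip(subs, offsets):
                for u, v, a in s.edges:
                    if a not in per_label:
                        raise ValueError(f"edge label {a!r} not in configured label set {cfg.labels}")
                    rows, cols = per_label[a]
                    rows.append(off + v)  # message u -> v lands in row v
                    cols.append(off + u)
            keys = list(cfg.labels) if cfg.edge_aware else ["__all__"]
            if not cfg.edge_aware:
                rows = [r for a in cfg.labels for r in per_label[a][0]]
                cols = [c for a in cfg.labels for c in per_label[a][1]]
                per_label = {"__all__": (rows, cols)}
            for a in keys:
                rows, cols = per_label[a]
                m = sp.coo_matrix(
                    (np.ones(len(rows)), (rows, cols)), shape=(n, n)
                ).tocsr()
                self.adj[a] = m
                self.adj_t[a] = m.T.tocsr()

    def pool(self, h: np.ndarray) -> np.ndarray:
        acc = np.zeros((self.n_graphs, h.shape[1]))
        np.add.at(acc, self.graph_id, h)
        return acc / self.sizes[:, None]


# ---------------------------------------------------------------------------
# Forward / backward


def _forward_batch(params: ModelParams, cfg: ModelConfig, batch: GraphBatch, training: bool, keep_cache: bool):
    """Run the network; return (probabilities, h_g, cache)."""
    t, run = params.tensors, params.running
    h = batch.X
    pooled = []
    cache = [] if keep_cache else None
    node_embs = []
    for layer in range(cfg.layers):
        z = h @ t[f"W{layer}"].T
        agg = {}
        if cfg.edge_aware:
            for a in cfg.labels:
                m = batch.adj[a] @ h
                agg[a] = m
                z = z + m @ t[f"E:{a}:{layer}"].T
        elif cfg.uses_edges:
            m = batch.adj["__all__"] @ h
            agg["__all__"] = m
            z = z + m @ t[f"U{layer}"].T
        r = np.maximum(z, 0.0)
        if training:
            mu = r.mean(axis=0)
            var = r.var(axis=0)
            run[f"mean{layer}"] = (1 - _BN_MOMENTUM) * run[f"mean{layer}"] + _BN_MOMENTUM * mu
            run[f"var{layer}"] = (1 - _BN_MOMENTUM) * run[f"var{layer}"] + _BN_MOMENTUM * var
        else:
            mu = run[f"mean{layer}"]
            var = run[f"var{layer}"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        r_hat = (r - mu) * inv_std
        h_next = t[f"gamma{layer}"] * r_hat + t[f"beta{layer}"]
        if keep_cache:
            cache.append({"h_in": h, "z": z, "r_hat": r_hat, "inv_std": inv_std, "agg": agg})
        node_embs.append(h_next)
        pooled.append(batch.pool(h_next))
        h = h_next
    h_g = np.hstack(pooled)  # (B, d*L)
    logits = h_g @ t["w_out"] + t["b_out"][0]
    prob = 1.0 / (1.0 + np.exp(-logits))
    return prob, h_g, cache, node_embs


def _backward_batch(params, cfg, batch, y, prob, h_g, cache):
    """Gradients of the mean BCE loss w.r.t. every trainable tensor."""
    t = params.tensors
    grads = {k: np.zeros_like(v) for k, v in t.items()}
    B = batch.n_graphs
    d = cfg.d
    dlogits = (prob - y) / B  # BCE-through-sigmoid
    grads["w_out"] = h_g.T @ dlogits
    grads["b_out"] = np.array([dlogits.sum()])
    dh_g = np.outer(dlogits, t["w_out"])  # (B, d*L)

    dh_next = np.zeros((batch.n_nodes, d))  # grad flowing from layer l+1
    for layer in reversed(range(cfg.layers)):
        c = cache[layer]
        dpool = dh_g[:, layer * d : (layer + 1) * d]
        dh = dh_next + dpool[batch.graph_id] / batch.sizes[batch.graph_id, None]
        # batch norm (training statistics)
        grads[f"beta{layer}"] = dh.sum(axis=0)
        grads[f"gamma{layer}"] = (dh * c["r_hat"]).sum(axis=0)
        dr_hat = dh * t[f"gamma{layer}"]
        n = dh.shape[0]
        dr = (
            c["inv_std"]
            / n
            * (n * dr_hat - dr_hat.sum(axis=0) - c["r_hat"] * (dr_hat * c["r_hat"]).sum(axis=0))
        )
        dz = dr * (c["z"] > 0)
        grads[f"W{layer}"] = dz.T @ c["h_in"]
        dh_in = dz @ t[f"W{layer}"]
        if cfg.edge_aware:
            for a in cfg.labels:
                grads[f"E:{a}:{layer}"] = dz.T @ c["agg"][a]
                dh_in = dh_in + (batch.adj_t[a] @ dz) @ t[f"E:{a}:{layer}"]
        elif cfg.uses_edges:
            grads[f"U{layer}"] = dz.T @ c["agg"]["__all__"]
            dh_in = dh_in + (batch.adj_t["__all__"] @ dz) @ t[f"U{layer}"]
        dh_next = dh_in
    return grads


def forward(params: ModelParams, cfg: ModelConfig, sub: IOSubgraph, training: bool = False) -> Prediction:
    """Predict one subgraph; inference mode uses running BN statistics."""
    batch = GraphBatch([sub], cfg)
    prob, h_g, _, node_embs = _forward_batch(params, cfg, batch, training, keep_cache=False)
    return Prediction(float(prob[0]), h_g[0], node_embs)


def predict(params: ModelParams, cfg: ModelConfig, subs: list[IOSubgraph]) -> np.ndarray:
    """Inference-mode probabilities for a list of subgraphs."""
    if not subs:
        return np.empty(0)
    batch = GraphBatch(subs, cfg)
    prob, _, _, _ = _forward_batch(params, cfg, batch, training=False, keep_cache=False)
    return prob


def loss(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Binary cross-entropy, averaged over the dataset:
    -(1/|D|) sum [y log p + (1-y) log(1-p)], probabilities clamped to
    [1e-7, 1-1e-7]."""
    p = np.clip(np.asarray(predictions, dtype=float), _CLAMP, 1 - _CLAMP)
    y = np.asarray(labels, dtype=float)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# Training


class _Adam:
    def __init__(self, tensors: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in tensors.items()}
        self.v = {k: np.zeros_like(v) for k, v in tensors.items()}
        self.t = 0

    def step(self, tensors: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in tensors:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            tensors[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def class_balanced_weights(labels: np.ndarray) -> np.ndarray:
    """Per-example sampling weights inversely proportional to class
    frequency (the weighted-sampler-with-replacement scheme)."""
    labels = np.asarray(labels)
    counts = np.bincount(labels.astype(int), minlength=2)
    w = np.where(labels == 1, 1.0 / max(counts[1], 1), 1.0 / max(counts[0], 1))
    return w / w.sum()


def train(
    cfg: ModelConfig,
    data: list[LabeledExample],
    validation: list[LabeledExample] | None = None,
) -> tuple[ModelParams, list[dict]]:
    """Train by Adam-flavored stochastic gradient descent.

    Batches are drawn by sampling with replacement, each example weighted
    inversely to its class frequency, which evens out class imbalance in
    expectation.  Returns the parameters of the epoch with the best
    validation AUROC (final parameters when no validation set is given)
    plus a per-epoch history of training loss and validation AUROC.
    Fully deterministic given ``cfg.seed``.
    """
    from .evaluation import auroc  # local import to avoid a module cycle

    if not data:
        raise ValueError("empty training data")
    y_all = np.array([e.y for e in data])
    if len(np.unique(y_all)) < 2:
        raise ValueError("training data contains a single class; cannot train a classifier")

    rng = np.random.default_rng(cfg.seed)
    params = init_params(cfg, rng)
    opt = _Adam(params.tensors, cfg.lr)
    weights = class_balanced_weights(y_all)
    val_subs = [e.subgraph for e in validation] if validation else None
    val_y = np.array([e.y for e in validation]) if validation else None

    history: list[dict] = []
    best = params.copy()
    best_auroc = -np.inf
    n = len(data)
    for epoch in range(cfg.epochs):
        order = rng.choice(n, size=n, replace=True, p=weights)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            subs = [data[i].subgraph for i in idx]
            y = y_all[idx].astype(float)
            batch = GraphBatch(subs, cfg)
            prob, h_g, cache, _ = _forward_batch(params, cfg, batch, training=True, keep_cache=True)
            grads = _backward_batch(params, cfg, batch, y, prob, h_g, cache)
            opt.step(params.tensors, grads)
            epoch_loss += loss(prob, y)
            n_batches += 1
        entry = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if val_subs is not None:
            val_prob = predict(params, cfg, val_subs)
            score = auroc(val_y, val_prob)  # None on a single-class validation set
            entry["val_auroc"] = score
            if score is not None and score > best_auroc:
                best_auroc = score
                best = params.copy()
        history.append(entry)
    if val_subs is None or best_auroc == -np.inf:
        best = params
    return best, history


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(params: ModelParams, cfg: ModelConfig, path: str | Path) -> None:
    """Versioned JSON container: config, label ordering, all tensors.

    Edge matrices are keyed by label *name*, so the label-set ordering is
    part of the contract and survives round-trips.
    """
    payload = {
        "format": "petridyn-checkpoint",
        "version": 1,
        "config": asdict(cfg),
        "tensors": {k: v.tolist() for k, v in params.tensors.items()},
        "running": {k: v.tolist() for k, v in params.running.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[ModelParams, ModelConfig]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "petridyn-checkpoint" or payload.get("version") != 1:
        raise ValueError("not a petridyn checkpoint (or unsupported version)")
    cfg_dict = payload["config"]
    cfg_dict["labels"] = tuple(cfg_dict["labels"])
    cfg = ModelConfig(**cfg_dict)
    params = ModelParams(
        {k: np.array(v) for k, v in payload["tensors"].items()},
        {k: np.array(v) for k, v in payload["running"].items()},
    )
    return params, cfg
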