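"""Node-classification architectures over edge-list message passing.

Three full-batch models share one interface: graph convolution with
symmetric degree normalization (GCN), mean-aggregator neighborhood
layers (GraphSAGE), and multi-head dot-product attention restricted to
graph neighbors with residual connections and layer normalization
(graph transformer).  Forward passes accept optional per-edge and
per-feature soft masks, which is what the explainer differentiates
through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ._autodiff import DTYPE, Tensor, spmm

__all__ = ["TrainConfig", "init_model", "GCN", "GraphSAGE", "GraphTransformer"]

ARCHITECTURES = ("gcn", "graphsage", "graph_transformer")


@dataclass
class TrainConfig:
    arch: str = "graphsage"
    num_layers: int = 2
    hidden_dim: int = 16
    num_heads: int = 2  # transformer only
    dropout: float = 0.1
    learning_rate: float = 0.001
    epochs: int = 500
    seed: int = 0
    init: str = "glorot"  # or "ones" for constant-initialization experiments

    def validate(self) -> None:
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown arch {self.arch!r}; choose from {ARCHITECTURES}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")


def _init_weight(rng: np.random.Generator, fan_in: int, fan_out: int, mode: str) -> Tensor:
    if mode == "ones":
        value = np.ones((fan_in, fan_out))
    else:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        value = rng.uniform(-limit, limit, size=(fan_in, fan_out))
    return Tensor(value, requires_grad=True)


def _init_bias(fan_out: int, mode: str) -> Tensor:
    value = np.ones(fan_out) if mode == "ones" else np.zeros(fan_out)
    return Tensor(value, requires_grad=True)


def _dropout(h: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0 or rng is None:
        return h
    keep = (rng.random(h.value.shape) >= rate) / (1.0 - rate)
    return h * Tensor(keep)


class _Base:
    """Shared plumbing: parameter registry and mask handling."""

    def __init__(self) -> None:
        self.params: list[Tensor] = []

    def _linear(self, rng, fan_in, fan_out, mode) -> tuple[Tensor, Tensor]:
        w = _init_weight(rng, fan_in, fan_out, mode)
        b = _init_bias(fan_out, mode)
        self.params += [w, b]
        return w, b

    @staticmethod
    def _effective_inputs(x, weights, feature_mask, edge_mask):
        x_t = x if isinstance(x, Tensor) else Tensor(x)
        if feature_mask is not None:
            x_t = x_t * feature_mask
        w_t = weights if isinstance(weights, Tensor) else Tensor(np.asarray(weights).reshape(-1, 1))
        if w_t.value.ndim == 1:
            w_t = w_t.reshape(-1, 1)
        if edge_mask is not None:
            em = edge_mask if edge_mask.value.ndim == 2 else edge_mask.reshape(-1, 1)
            w_t = w_t * em
        return x_t, w_t


class GCN(_Base):
    """Stacked graph convolutions with symmetric degree normalization.

    Message coefficients are 1/sqrt(d_src * d_dst) with degrees counted
    on the provided edge list (self-loops included when the graph has
    them), times the per-edge weight.
    """

    def __init__(self, in_dim: int, num_classes: int, config: TrainConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        dims = [in_dim] + [config.hidden_dim] * config.num_layers + [num_classes]
        self.layers = [
            self._linear(rng, dims[i], dims[i + 1], config.init)
            for i in range(len(dims) - 1)
        ]

    def forward(self, x, edges, weights, training=False, rng=None,
                feature_mask=None, edge_mask=None) -> Tensor:
        x_t, w_t = self._effective_inputs(x, weights, feature_mask, edge_mask)
        n = x_t.value.shape[0]
        src, dst = edges[:, 0], edges[:, 1]
        deg = np.zeros(n)
        np.add.at(deg, dst, 1.0)
        deg = np.maximum(deg, 1.0)
        norm_val = (1.0 / np.sqrt(deg[src] * deg[dst])).astype(DTYPE)
        agg_sparse = None
        if edge_mask is None:
            # fixed adjacency: fold norm and weights into one sparse matrix
            agg_sparse = sparse.csr_matrix(
                (norm_val * w_t.value.ravel(), (dst, src)), shape=(n, n)
            )
        else:
            norm = Tensor(norm_val.reshape(-1, 1))
        h = x_t
        for i, (w, b) in enumerate(self.layers):
            if agg_sparse is not None:
                h = spmm(agg_sparse, h) @ w + b
            else:
                msg = h.gather(src) * norm * w_t
                h = msg.segment_sum(dst, n) @ w + b
            if i < len(self.layers) - 1:
                h = h.relu()
                if training:
                    h = _dropout(h, self.config.dropout, rng)
        return h


class GraphSAGE(_Base):
    """Mean-aggregator layers: h' = ReLU(W_self h + W_neigh mean_N(h))."""

    def __init__(self, in_dim: int, num_classes: int, config: TrainConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        dims = [in_dim] + [config.hidden_dim] * config.num_layers + [num_classes]
        self.layers = []
        for i in range(len(dims) - 1):
            w_self, b = self._linear(rng, dims[i], dims[i + 1], config.init)
            w_neigh = _init_weight(rng, dims[i], dims[i + 1], config.init)
            self.params.append(w_neigh)
            self.layers.append((w_self, w_neigh, b))

    def forward(self, x, edges, weights, training=False, rng=None,
                feature_mask=None, edge_mask=None) -> Tensor:
        x_t, w_t = self._effective_inputs(x, weights, feature_mask, edge_mask)
        n = x_t.value.shape[0]
        src, dst = edges[:, 0], edges[:, 1]
        mean_sparse = None
        if edge_mask is None:
            wsum = np.zeros(n)
            np.add.at(wsum, dst, w_t.value.ravel())
            inv = (1.0 / np.maximum(wsum, 1e-9)).astype(DTYPE)
            mean_sparse = sparse.csr_matrix(
                (w_t.value.ravel() * inv[dst], (dst, src)), shape=(n, n)
            )
        h = x_t
        for i, (w_self, w_neigh, b) in enumerate(self.layers):
            if mean_sparse is not None:
                neigh = spmm(mean_sparse, h)
            else:
                neigh_sum = (h.gather(src) * w_t).segment_sum(dst, n)
                denom = w_t.segment_sum(dst, n) + 1e-9
                neigh = neigh_sum / denom
            h = h @ w_self + neigh @ w_neigh + b
            if i < len(self.layers) - 1:
                h = h.relu()
                if training:
                    h = _dropout(h, self.config.dropout, rng)
        return h


class GraphTransformer(_Base):
    """Neighborhood-restricted multi-head attention blocks.

    Attention is computed per edge (dot-product of destination query and
    source key, softmax over each destination's incoming edges), so the
    graph's sparsity is the attention mask.  Each block is attention +
    residual + layer norm, then a ReLU feed-forward + residual + layer
    norm.  Per-edge weights/masks multiply the unnormalized attention,
    i.e. act like a soft adjacency.
    """

    def __init__(self, in_dim: int, num_classes: int, config: TrainConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        d = config.hidden_dim
        h = config.num_heads
        if d % h != 0:
            raise ValueError("hidden_dim must be divisible by num_heads")
        self.d_head = d // h
        self.w_in, self.b_in = self._linear(rng, in_dim, d, config.init)
        self.blocks = []
        for _ in range(config.num_layers):
            wq, bq = self._linear(rng, d, d, config.init)
            wk, bk = self._linear(rng, d, d, config.init)
            wv, bv = self._linear(rng, d, d, config.init)
            wo, bo = self._linear(rng, d, d, config.init)
            wf1, bf1 = self._linear(rng, d, 2 * d, config.init)
            wf2, bf2 = self._linear(rng, 2 * d, d, config.init)
            self.blocks.append((wq, bq, wk, bk, wv, bv, wo, bo, wf1, bf1, wf2, bf2))
        self.w_out, self.b_out = self._linear(rng, d, num_classes, config.init)

    def forward(self, x, edges, weights, training=False, rng=None,
                feature_mask=None, edge_mask=None) -> Tensor:
        x_t, w_t = self._effective_inputs(x, weights, feature_mask, edge_mask)
        n = x_t.value.shape[0]
        src, dst = edges[:, 0], edges[:, 1]
        n_edges = len(edges)
        n_heads, d_head = self.config.num_heads, self.d_head
        # fixed gather/scatter operators, built once per pass
        ones = np.ones(n_edges, dtype=DTYPE)
        g_src = sparse.csr_matrix((ones, (np.arange(n_edges), src)), shape=(n_edges, n))
        g_dst = sparse.csr_matrix((ones, (np.arange(n_edges), dst)), shape=(n_edges, n))
        s_dst = sparse.csr_matrix((ones, (dst, np.arange(n_edges))), shape=(n, n_edges))
        h = (x_t @ self.w_in + self.b_in).relu()
        for wq, bq, wk, bk, wv, bv, wo, bo, wf1, bf1, wf2, bf2 in self.blocks:
            q = spmm(g_dst, h @ wq + bq).reshape(-1, n_heads, d_head)
            k = spmm(g_src, h @ wk + bk).reshape(-1, n_heads, d_head)
            v = spmm(g_src, h @ wv + bv).reshape(-1, n_heads, d_head)
            score = (q * k).sum(axis=-1) * (1.0 / np.sqrt(d_head))  # (E, heads)
            # stabilize with a detached per-destination max
            shift = np.full((n, n_heads), -np.inf)
            np.maximum.at(shift, dst, score.value)
            shift = np.where(np.isfinite(shift), shift, 0.0)
            ex = (score - Tensor(shift[dst])).exp() * w_t  # soft adjacency
            denom = spmm(s_dst, ex) + 1e-16
            alpha = ex / spmm(g_dst, denom)
            mixed = spmm(s_dst, (v * alpha.reshape(-1, n_heads, 1)).reshape(-1, n_heads * d_head))
            attn = mixed @ wo + bo
            if training:
                attn = _dropout(attn, self.config.dropout, rng)
            h = (h + attn).layer_norm()
            ffn = ((h @ wf1 + bf1).relu()) @ wf2 + bf2
            if training:
                ffn = _dropout(ffn, self.config.dropout, rng)
            h = (h + ffn).layer_norm()
        return h @ self.w_out + self.b_out


def init_model(arch: str, in_dim: int, num_classes: int, config: TrainConfig):
    """Build a seeded model of the requested architecture."""
    config.validate()
    if in_dim < 1 or num_classes < 1:
        raise ValueError("in_dim and num_classes must be >= 1")
    if arch != config.arch:
        config = TrainConfig(**{**config.__dict__, "arch": arch})
    rng = np.random.default_rng(config.seed)
    cls = {"gcn": GCN, "graphsage": GraphSAGE, "graph_transformer": GraphTransformer}[
        config.arch
    ]
    return cls(in_dim, num_classes, config, rng)
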