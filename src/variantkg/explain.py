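"""Per-node interpretability via learned soft edge and feature masks.

For a trained model and a target node, the explainer extracts the
k-hop subgraph around the node (edges treated as undirected for
reachability, matching message flow on bidirectional graphs), then
learns sigmoid-parameterized masks over the subgraph's edges and over
the feature columns by gradient descent.  The objective keeps the
model's original prediction for the node under masking (cross-entropy
to the original label) while shrinking the masks (L1 size penalties)
and pushing them toward binary (entropy penalty).  Features are then
ranked by their learned mask weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gnn._autodiff import Adam, Tensor
from .graph_build import LearningGraph

__all__ = [
    "ExplainConfig",
    "Explanation",
    "khop_subgraph",
    "explain_node",
    "top_features",
    "explanation_to_dot",
]


@dataclass
class ExplainConfig:
    """Mask-learning hyperparameters.

    The feature size penalty is deliberately strong: with weak sparsity
    pressure every mask drifts down uniformly and the ranking reflects
    initialization noise; a strong penalty prunes features the
    prediction can survive without, so only load-bearing ones keep high
    mask weight.
    """

    epochs: int = 200
    learning_rate: float = 0.02
    edge_size_penalty: float = 0.005
    feature_size_penalty: float = 0.3
    entropy_penalty: float = 0.1
    seed: int = 0


@dataclass
class Explanation:
    node_id: int
    k: int
    subgraph_nodes: np.ndarray  # original node ids
    subgraph_edges: np.ndarray  # (E_sub, 2) original node ids
    edge_mask: np.ndarray  # in [0, 1], aligned to subgraph_edges
    feature_mask: np.ndarray  # in [0, 1], aligned to feature_names
    top_features: list[str]
    feature_names: list[str] = field(default_factory=list)
    predicted_class: int = 0
    loss_curve: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "node_id": int(self.node_id),
            "k": int(self.k),
            "subgraph_nodes": self.subgraph_nodes.tolist(),
            "subgraph_edges": self.subgraph_edges.tolist(),
            "edge_mask": self.edge_mask.tolist(),
            "feature_mask": self.feature_mask.tolist(),
            "top_features": list(self.top_features),
            "predicted_class": int(self.predicted_class),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def khop_subgraph(
    graph: LearningGraph, node_id: int, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Nodes within k undirected hops of ``node_id`` and the induced edges.

    Returns (sorted node ids, edge-index array into ``graph.edges``).
    """
    if not 0 <= node_id < graph.num_nodes:
        raise ValueError(f"node_id {node_id} out of range [0, {graph.num_nodes})")
    if k < 0:
        raise ValueError("k must be >= 0")
    src, dst = graph.edges[:, 0], graph.edges[:, 1]
    reached = np.zeros(graph.num_nodes, dtype=bool)
    frontier = np.zeros(graph.num_nodes, dtype=bool)
    reached[node_id] = frontier[node_id] = True
    for _ in range(k):
        nxt = np.zeros(graph.num_nodes, dtype=bool)
        touching = frontier[src] | frontier[dst]
        nxt[src[touching]] = True
        nxt[dst[touching]] = True
        frontier = nxt & ~reached
        reached |= frontier
        if not frontier.any():
            break
    nodes = np.flatnonzero(reached).astype(np.int64)
    edge_idx = np.flatnonzero(reached[src] & reached[dst]).astype(np.int64)
    return nodes, edge_idx


def explain_node(
    model,
    graph: LearningGraph,
    node_id: int,
    k: int = 2,
    config: ExplainConfig | None = None,
) -> Explanation:
    """Learn edge/feature masks that preserve the model's prediction for
    one node on its k-hop subgraph."""
    import warnings

    config = config or ExplainConfig()
    nodes, edge_idx = khop_subgraph(graph, node_id, k)
    if len(nodes) == 1 and len(edge_idx) == 0:
        warnings.warn(f"node {node_id} is isolated; explaining over the single node")

    relabel = {int(orig): i for i, orig in enumerate(nodes)}
    sub_edges = np.array(
        [[relabel[int(s)], relabel[int(d)]] for s, d in graph.edges[edge_idx]],
        dtype=np.int64,
    ).reshape(-1, 2)
    sub_weights = graph.weights[edge_idx]
    sub_x = graph.node_features[nodes]
    target = relabel[node_id]

    original_logits = model.forward(graph.node_features, graph.edges, graph.weights)
    predicted = int(original_logits.value[node_id].argmax())

    rng = np.random.default_rng(config.seed)
    n_features = graph.node_features.shape[1]
    # edges get a small symmetry-breaking jitter; the feature mask starts
    # uniform so its final ranking reflects gradients only
    edge_logits = Tensor(rng.normal(1.0, 0.1, size=(max(len(sub_edges), 1), 1)), requires_grad=True)
    feat_logits = Tensor(np.full((1, n_features), 1.0), requires_grad=True)
    opt = Adam([edge_logits, feat_logits], lr=config.learning_rate)

    onehot = np.zeros(original_logits.value.shape[1])
    onehot[predicted] = 1.0
    loss_curve: list[float] = []
    for _ in range(config.epochs):
        edge_mask = edge_logits.sigmoid()
        feat_mask = feat_logits.sigmoid()
        logits = model.forward(
            sub_x,
            sub_edges if len(sub_edges) else np.zeros((0, 2), dtype=np.int64),
            sub_weights if len(sub_weights) else np.zeros(0),
            feature_mask=feat_mask,
            edge_mask=edge_mask if len(sub_edges) else None,
        )
        logp = logits.gather(np.array([target])).log_softmax()
        pred_loss = -(logp * Tensor(onehot.reshape(1, -1))).sum()

        def _mask_penalty(mask: Tensor, size_coef: float) -> Tensor:
            size = mask.sum() * size_coef
            m = mask * 0.99 + 0.005  # keep entropy finite at the rails
            ent = -(m * m.log() + (1.0 - m) * (1.0 - m).log()).mean()
            return size + ent * config.entropy_penalty

        loss = pred_loss + _mask_penalty(feat_mask, config.feature_size_penalty)
        if len(sub_edges):
            loss = loss + _mask_penalty(edge_mask, config.edge_size_penalty)
        opt.zero_grad()
        loss.backward()
        opt.step()
        loss_curve.append(float(loss.value))

    feature_mask = feat_logits.sigmoid().value.ravel()
    edge_mask = edge_logits.sigmoid().value.ravel()[: len(sub_edges)]
    order = np.argsort(-feature_mask)
    names = list(graph.feature_names)
    return Explanation(
        node_id=node_id,
        k=k,
        subgraph_nodes=nodes,
        subgraph_edges=graph.edges[edge_idx],
        edge_mask=edge_mask,
        feature_mask=feature_mask,
        top_features=[names[i] for i in order],
        feature_names=names,
        predicted_class=predicted,
        loss_curve=loss_curve,
    )


def top_features(explanations: list[Explanation], n: int = 5) -> list[str]:
    """Global ranking by mean feature-mask weight across explanations."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not explanations:
        return []
    mean_mask = np.mean([e.feature_mask for e in explanations], axis=0)
    names = explanations[0].feature_names
    order = np.argsort(-mean_mask)
    return [names[i] for i in order[:n]]


def explanation_to_dot(explanation: Explanation, threshold: float = 0.5) -> str:
    """Graphviz DOT rendering of the masked subgraph (edges above the
    mask threshold solid, others dotted; target node doubled)."""
    lines = ["digraph explanation {"]
    for node in explanation.subgraph_nodes:
        shape = "doublecircle" if int(node) == explanation.node_id else "circle"
        lines.append(f'  n{int(node)} [shape={shape}];')
    for (s, d), m in zip(explanation.subgraph_edges, explanation.edge_mask):
        style = "solid" if m >= threshold else "dotted"
        lines.append(f'  n{int(s)} -> n{int(d)} [style={style}, label="{m:.2f}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
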