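"""From feature table to integer-encoded homogeneous learning graph.

Nodes are feature-table rows (the same genomic variant seen in two
patients yields two nodes).  Edges connect nodes sharing a gene name
(clique per gene, the default) or everything to everything; the graph is
homogeneous with a single edge type.  Categorical columns are
integer-coded by first appearance, numeric columns parsed as floats and
(by default) z-standardized; both encodings are stored so the graph is
invertible back to the source strings.  Train/validation/test node
masks come from a seeded uniform permutation with an 80:10:10 default
split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .vcf_io import parse_ann

__all__ = [
    "GraphConfig",
    "LearningGraph",
    "DEFAULT_FEATURES",
    "NUMERIC_COLUMNS",
    "derive_label",
    "encode_features",
    "build_edges",
    "split_masks",
    "build_learning_graph",
    "gene_from_ann",
]

IMPACT_ORDER = ("HIGH", "MODERATE", "LOW", "MODIFIER")

NUMERIC_COLUMNS = {
    "position",
    "quality",
    "allele_count",
    "allele_frequency",
    "total_number_of_alleles",
    "baseqranksum",
    "depth",
    "excesshet",
    "fs",
    "mleac",
    "mleaf",
    "RMS_mapping_quality",
    "qd",
    "readposranksum",
    "sor",
    "combined_depth",
    "conditional_genotype_quality",
    "raw_score",
    "phred_score",
}

DEFAULT_FEATURES = [
    "chromosome",
    "position",
    "ref_genome",
    "alt_genome",
    "quality",
    "allele_count",
    "allele_frequency",
    "total_number_of_alleles",
    "baseqranksum",
    "depth",
    "excesshet",
    "fs",
    "mleac",
    "mleaf",
    "RMS_mapping_quality",
    "qd",
    "readposranksum",
    "sor",
    "combined_depth",
    "conditional_genotype_quality",
    "genotype",
    "raw_score",
    "phred_score",
]

#: columns that would leak each label into the features
_LABEL_SOURCES = {
    "putative_impact": {"ann", "ann_split_1"},
    "cadd_category": {"ann", "phred_score"},
}


@dataclass
class GraphConfig:
    edge_type: str = "gene_name"  # or "fully_connected"
    bidirectional: bool = True
    weight_mode: str = "constant_one"  # or "in_degree" / "user_value"
    user_weight: float = 1.0
    train_frac: float = 0.8
    val_frac: float = 0.1
    seed: int = 0
    label: str = "putative_impact"  # or "cadd_category" / a categorical column
    cadd_bin_edges: tuple[float, ...] = (10.0, 20.0, 30.0)
    add_self_loops: bool = True
    standardize: bool = True

    def validate(self) -> None:
        if self.edge_type not in ("gene_name", "fully_connected"):
            raise ValueError(f"unknown edge_type {self.edge_type!r}")
        if self.weight_mode not in ("constant_one", "in_degree", "user_value"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.train_frac + self.val_frac > 1.0 + 1e-12:
            raise ValueError("train_frac + val_frac must be <= 1")
        if any(a >= b for a, b in zip(self.cadd_bin_edges, self.cadd_bin_edges[1:])):
            raise ValueError("cadd_bin_edges must be strictly ascending")


@dataclass
class LearningGraph:
    num_nodes: int
    node_features: np.ndarray  # (n, d) float
    labels: np.ndarray  # (n,) int
    edges: np.ndarray  # (E, 2) int, src -> dst
    weights: np.ndarray  # (E,) float
    train_mask: np.ndarray
    val_mask: np.ndarray
    test_mask: np.ndarray
    encoders: dict[str, dict[str, int]]
    scalers: dict[str, tuple[float, float]]  # numeric column -> (mean, std)
    label_names: list[str]
    feature_names: list[str]

    def summary(self) -> dict:
        return {
            "features": list(self.feature_names),
            "label_names": list(self.label_names),
            "num_classes": len(self.label_names),
            "num_nodes": int(self.num_nodes),
            "num_edges": int(len(self.edges)),
            "train_nodes": int(self.train_mask.sum()),
            "val_nodes": int(self.val_mask.sum()),
            "test_nodes": int(self.test_mask.sum()),
        }

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(
            out / "graph.npz",
            node_features=self.node_features,
            labels=self.labels,
            edges=self.edges,
            weights=self.weights,
            train_mask=self.train_mask,
            val_mask=self.val_mask,
            test_mask=self.test_mask,
        )
        pd.DataFrame(self.edges, columns=["src", "dst"]).assign(
            weight=self.weights
        ).to_csv(out / "edges.csv", index=False)
        meta = {
            "encoders": self.encoders,
            "scalers": {k: list(v) for k, v in self.scalers.items()},
            "label_names": self.label_names,
            "feature_names": self.feature_names,
            "summary": self.summary(),
        }
        (out / "graph_meta.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, out_dir: str | Path) -> "LearningGraph":
        out = Path(out_dir)
        arrays = np.load(out / "graph.npz")
        meta = json.loads((out / "graph_meta.json").read_text())
        return cls(
            num_nodes=int(arrays["labels"].shape[0]),
            node_features=arrays["node_features"],
            labels=arrays["labels"],
            edges=arrays["edges"],
            weights=arrays["weights"],
            train_mask=arrays["train_mask"],
            val_mask=arrays["val_mask"],
            test_mask=arrays["test_mask"],
            encoders=meta["encoders"],
            scalers={k: tuple(v) for k, v in meta["scalers"].items()},
            label_names=meta["label_names"],
            feature_names=meta["feature_names"],
        )


def gene_from_ann(ann_split_1: str) -> str:
    """Gene name = 4th pipe field of the first annotation ('' if absent)."""
    if not ann_split_1:
        return ""
    try:
        return parse_ann(ann_split_1).gene_name
    except ValueError:
        return ""


def _cadd_bin_name(phred: float, edges: Sequence[float]) -> str:
    if phred < edges[0]:
        return f"<{edges[0]:g}"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= phred < hi:
            return f"{lo:g}-{hi:g}"
    return f">={edges[-1]:g}"


def derive_label(row, config: GraphConfig) -> str | None:
    """Class name for one table row, or None when the source is missing."""
    if config.label == "putative_impact":
        ann1 = row.get("ann_split_1", "")
        if not ann1:
            return None
        impact = parse_ann(ann1).putative_impact
        return impact or None
    if config.label == "cadd_category":
        phred = row.get("phred_score", "")
        if phred in ("", None):
            return None
        return _cadd_bin_name(float(phred), config.cadd_bin_edges)
    value = row.get(config.label, "")
    return value or None


def _label_names_for(config: GraphConfig, observed: list[str]) -> list[str]:
    if config.label == "putative_impact":
        return [c for c in IMPACT_ORDER if c in observed]
    if config.label == "cadd_category":
        edges = config.cadd_bin_edges
        ordered = [f"<{edges[0]:g}"]
        ordered += [f"{lo:g}-{hi:g}" for lo, hi in zip(edges, edges[1:])]
        ordered.append(f">={edges[-1]:g}")
        return [c for c in ordered if c in observed]
    return sorted(set(observed))


def encode_features(
    table: pd.DataFrame,
    feature_names: Sequence[str],
    config: GraphConfig,
) -> tuple[np.ndarray, dict, dict, np.ndarray, list[str], np.ndarray]:
    """Derive labels, drop unlabeled rows, and integer/float-encode features.

    Returns (matrix, encoders, scalers, labels, label_names, kept_index).
    Raises when a feature would leak the label (the raw ``ann`` text is
    never allowed as a feature).
    """
    forbidden = _LABEL_SOURCES.get(config.label, {"ann", config.label})
    leak = [f for f in feature_names if f in forbidden or f == config.label]
    if leak:
        raise ValueError(
            f"feature(s) {leak} would leak label {config.label!r}; remove them"
        )
    if "ann" in feature_names:
        raise ValueError("raw 'ann' text cannot be used as a feature")

    class_names: list[str] = []
    labels_raw: list[str] = []
    kept: list[int] = []
    for i, (_, row) in enumerate(table.iterrows()):
        name = derive_label(row, config)
        if name is None:
            continue
        kept.append(i)
        labels_raw.append(name)
    n_dropped = len(table) - len(kept)
    if not kept:
        raise ValueError("all rows dropped: no usable label source")
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "dropped %d rows lacking label %s", n_dropped, config.label
        )
    class_names = _label_names_for(config, labels_raw)
    label_codes = {c: i for i, c in enumerate(class_names)}
    labels = np.array([label_codes[c] for c in labels_raw], dtype=np.int64)

    sub = table.iloc[kept]
    columns: list[np.ndarray] = []
    encoders: dict[str, dict[str, int]] = {}
    scalers: dict[str, tuple[float, float]] = {}
    for name in feature_names:
        if name not in table.columns:
            raise ValueError(f"feature {name!r} not in table columns")
        values = sub[name].tolist()
        if name in NUMERIC_COLUMNS:
            col = np.array(
                [float(v) if v not in ("", None) else 0.0 for v in values],
                dtype=np.float64,
            )
            if config.standardize:
                mean, std = float(col.mean()), float(col.std())
                std = std if std > 0 else 1.0
                scalers[name] = (mean, std)
                col = (col - mean) / std
            columns.append(col)
        else:
            codes = {}
            coded = np.empty(len(values), dtype=np.float64)
            for j, v in enumerate(values):
                key = v if v not in ("", None) else "None"
                if key not in codes:
                    codes[key] = len(codes)
                coded[j] = codes[key]
            encoders[name] = codes
            columns.append(coded)
    matrix = np.stack(columns, axis=1) if columns else np.zeros((len(kept), 0))
    return matrix, encoders, scalers, labels, class_names, np.array(kept)


def build_edges(
    rows: pd.DataFrame | Sequence[str], config: GraphConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Directed edge list and weights for the given nodes.

    ``rows`` is either the (label-filtered) feature table or a sequence
    of per-node gene names.  Gene mode links every unordered pair of
    nodes sharing a nonempty gene name, oriented low-id -> high-id, plus
    the reverse when bidirectional; fully-connected mode emits all
    n(n-1) ordered pairs.  Self-loops, when configured, are appended
    last with weight 1.0.
    """
    if isinstance(rows, pd.DataFrame):
        genes = [gene_from_ann(a) for a in rows["ann_split_1"].tolist()]
    else:
        genes = list(rows)
    n = len(genes)
    if n < 1:
        raise ValueError("need at least one node")

    pairs: list[tuple[int, int]] = []
    if config.edge_type == "fully_connected":
        for i in range(n):
            for j in range(n):
                if i != j:
                    pairs.append((i, j))
    else:
        by_gene: dict[str, list[int]] = {}
        for i, g in enumerate(genes):
            if g:
                by_gene.setdefault(g, []).append(i)
        for g in sorted(by_gene):
            members = by_gene[g]
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    i, j = members[a], members[b]
                    pairs.append((i, j))
                    if config.bidirectional:
                        pairs.append((j, i))

    edges = np.array(pairs, dtype=np.int64).reshape(-1, 2)
    if config.weight_mode == "constant_one":
        weights = np.ones(len(edges))
    elif config.weight_mode == "user_value":
        weights = np.full(len(edges), float(config.user_weight))
    else:  # in_degree of the destination node
        indeg = np.zeros(n, dtype=np.int64)
        if len(edges):
            np.add.at(indeg, edges[:, 1], 1)
        weights = indeg[edges[:, 1]].astype(np.float64) if len(edges) else np.zeros(0)

    if config.add_self_loops:
        loops = np.stack([np.arange(n), np.arange(n)], axis=1)
        edges = np.concatenate([edges, loops], axis=0)
        weights = np.concatenate([weights, np.ones(n)])
    return edges, weights


def split_masks(
    n: int, train_frac: float, val_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive boolean masks from a seeded permutation."""
    if n < 3:
        raise ValueError("need n >= 3 nodes to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_frac))
    n_val = int(np.floor(n * val_frac))
    train = np.zeros(n, dtype=bool)
    val = np.zeros(n, dtype=bool)
    test = np.zeros(n, dtype=bool)
    train[perm[:n_train]] = True
    val[perm[n_train : n_train + n_val]] = True
    test[perm[n_train + n_val :]] = True
    if not (train.any() and val.any() and test.any()):
        raise ValueError(
            "empty split mask; use more nodes or adjust train/val fractions"
        )
    return train, val, test


def build_learning_graph(
    table: pd.DataFrame,
    feature_names: Sequence[str] | None = None,
    config: GraphConfig | None = None,
) -> LearningGraph:
    """Compose labeling, encoding, edge construction, and splitting."""
    config = config or GraphConfig()
    config.validate()
    if feature_names is None:
        feature_names = [f for f in DEFAULT_FEATURES if f in table.columns]
        forbidden = _LABEL_SOURCES.get(config.label, {config.label})
        feature_names = [f for f in feature_names if f not in forbidden and f != config.label]
    matrix, encoders, scalers, labels, label_names, kept = encode_features(
        table, feature_names, config
    )
    sub = table.iloc[kept].reset_index(drop=True)
    edges, weights = build_edges(sub, config)
    train, val, test = split_masks(
        len(sub), config.train_frac, config.val_frac, config.seed
    )
    return LearningGraph(
        num_nodes=len(sub),
        node_features=matrix,
        labels=labels,
        edges=edges,
        weights=weights,
        train_mask=train,
        val_mask=val,
        test_mask=test,
        encoders=encoders,
        scalers=scalers,
        label_names=label_names,
        feature_names=list(feature_names),
    )
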