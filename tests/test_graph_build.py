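"""Learning-graph construction: labels, encoding, edges, splits."""

import numpy as np
import pandas as pd
import pytest

from variantkg.graph_build import (
    DEFAULT_FEATURES,
    GraphConfig,
    LearningGraph,
    build_edges,
    build_learning_graph,
    derive_label,
    encode_features,
    gene_from_ann,
    split_masks,
)

from ._oracles import oracle_gene_edges


def _row(**kw):
    return pd.Series(kw)


class TestDeriveLabel:
    def test_putative_impact_from_first_annotation(self):
        row = _row(ann_split_1="A|missense_variant|MODERATE|G1|ID1")
        assert derive_label(row, GraphConfig(label="putative_impact")) == "MODERATE"

    @pytest.mark.parametrize(
        "phred, expected", [(12.72, "10-20"), (5.0, "<10"), (25.0, "20-30"), (31.0, ">=30")]
    )
    def test_cadd_bins_with_default_edges(self, phred, expected):
        row = _row(phred_score=str(phred))
        assert derive_label(row, GraphConfig(label="cadd_category")) == expected

    def test_missing_source_returns_none(self):
        assert derive_label(_row(ann_split_1=""), GraphConfig(label="putative_impact")) is None
        assert derive_label(_row(phred_score=""), GraphConfig(label="cadd_category")) is None


class TestEncodeFeatures:
    def _table(self):
        return pd.DataFrame(
            {
                "ref_genome": ["G", "A", "G"],
                "quality": ["45.64", "12", ""],
                "ann_split_1": ["x|e|HIGH|G1", "x|e|LOW|G1", "x|e|HIGH|G2"],
                "genotype": ["0/1", "", "1/1"],
            }
        )

    def test_first_appearance_integer_codes(self):
        config = GraphConfig(label="putative_impact", standardize=False)
        matrix, encoders, _, labels, names, kept = encode_features(
            self._table(), ["ref_genome"], config
        )
        assert matrix[:, 0].tolist() == [0.0, 1.0, 0.0]
        assert encoders["ref_genome"] == {"G": 0, "A": 1}

    def test_numeric_parse_and_missing_to_zero(self):
        config = GraphConfig(label="putative_impact", standardize=False)
        matrix, _, _, _, _, _ = encode_features(self._table(), ["quality"], config)
        assert matrix[:, 0].tolist() == pytest.approx([45.64, 12.0, 0.0])

    def test_missing_categorical_coded_as_none(self):
        config = GraphConfig(label="putative_impact", standardize=False)
        _, encoders, _, _, _, _ = encode_features(self._table(), ["genotype"], config)
        assert "None" in encoders["genotype"]

    def test_label_source_in_features_is_leakage_error(self):
        config = GraphConfig(label="putative_impact")
        with pytest.raises(ValueError, match="leak"):
            encode_features(self._table(), ["ann_split_1"], config)

    def test_raw_ann_text_never_a_feature(self):
        table = self._table().assign(ann=["a", "b", "c"])
        with pytest.raises(ValueError):
            encode_features(table, ["ann"], GraphConfig(label="putative_impact"))

    def test_encoders_invert_back_to_source_strings(self, small_table):
        config = GraphConfig(label="putative_impact", standardize=False)
        features = ["chromosome", "ref_genome", "genotype"]
        matrix, encoders, _, _, _, kept = encode_features(small_table, features, config)
        sub = small_table.iloc[kept].reset_index(drop=True)
        for j, name in enumerate(features):
            decode = {v: k for k, v in encoders[name].items()}
            decoded = [decode[int(c)] for c in matrix[:, j]]
            source = [v if v != "" else "None" for v in sub[name]]
            assert decoded == source


class TestBuildEdges:
    def test_three_node_gene_clique_bidirectional(self):
        config = GraphConfig(bidirectional=True, add_self_loops=False)
        edges, weights = build_edges(["G1", "G1", "G1"], config)
        assert len(edges) == 6
        assert set(map(tuple, edges)) == {(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)}

    def test_unidirectional_orientation_low_to_high(self):
        config = GraphConfig(bidirectional=False, add_self_loops=False)
        edges, _ = build_edges(["G1", "G1", "G1"], config)
        assert set(map(tuple, edges)) == {(0, 1), (0, 2), (1, 2)}

    def test_fully_connected_has_n_times_n_minus_one_edges(self):
        config = GraphConfig(edge_type="fully_connected", add_self_loops=False)
        edges, _ = build_edges(["a", "b", "c", "d"], config)
        assert len(edges) == 12

    def test_single_node_with_self_loop(self):
        config = GraphConfig(add_self_loops=True)
        edges, weights = build_edges(["G1"], config)
        assert edges.tolist() == [[0, 0]]
        assert weights.tolist() == [1.0]

    @pytest.mark.parametrize("bidirectional", [True, False])
    def test_matches_brute_force_pair_enumeration(self, bidirectional):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in rng.integers(0, 5, size=40)] + [""]
        config = GraphConfig(bidirectional=bidirectional, add_self_loops=False)
        edges, _ = build_edges(genes, config)
        assert set(map(tuple, edges)) == oracle_gene_edges(genes, bidirectional)
        expected = sum(
            m * (m - 1) if bidirectional else m * (m - 1) // 2
            for m in pd.Series([g for g in genes if g]).value_counts()
        )
        assert len(edges) == expected

    def test_in_degree_weights_square_identity(self):
        # sum of weights into v equals in-degree(v)^2 by construction
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in rng.integers(0, 3, size=20)]
        config = GraphConfig(weight_mode="in_degree", add_self_loops=False)
        edges, weights = build_edges(genes, config)
        indeg = np.zeros(20)
        np.add.at(indeg, edges[:, 1], 1)
        into = np.zeros(20)
        np.add.at(into, edges[:, 1], weights)
        assert into == pytest.approx(indeg**2)

    def test_user_value_weights(self):
        config = GraphConfig(weight_mode="user_value", user_weight=2.5, add_self_loops=False)
        _, weights = build_edges(["G1", "G1"], config)
        assert set(weights.tolist()) == {2.5}

    def test_gene_extracted_from_first_annotation(self):
        assert gene_from_ann("A|eff|HIGH|GENE9|ID") == "GENE9"
        assert gene_from_ann("") == ""


class TestSplitMasks:
    def test_default_split_sizes(self):
        train, val, test = split_masks(100, 0.8, 0.1, seed=0)
        assert (train.sum(), val.sum(), test.sum()) == (80, 10, 10)

    def test_floor_behaviour_on_small_n(self):
        train, val, test = split_masks(10, 0.8, 0.1, seed=0)
        assert (train.sum(), val.sum(), test.sum()) == (8, 1, 1)

    def test_same_seed_identical_masks(self):
        a = split_masks(50, 0.8, 0.1, seed=7)
        b = split_masks(50, 0.8, 0.1, seed=7)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_masks_disjoint_and_exhaustive(self):
        train, val, test = split_masks(37, 0.6, 0.2, seed=3)
        combined = train.astype(int) + val.astype(int) + test.astype(int)
        assert (combined == 1).all()

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            split_masks(3, 0.98, 0.01, seed=0)


class TestBuildLearningGraph:
    def test_one_node_per_table_row(self, small_table, small_graph):
        assert small_graph.num_nodes == len(small_table)

    def test_summary_reports_task_and_graph_shape(self, small_graph):
        summary = small_graph.summary()
        assert summary["num_classes"] == len(small_graph.label_names)
        assert summary["num_nodes"] == small_graph.num_nodes
        assert summary["num_edges"] == len(small_graph.edges)
        assert set(summary["features"]) <= set(DEFAULT_FEATURES)

    def test_consecutive_node_ids_and_valid_labels(self, small_graph):
        assert small_graph.edges.max() < small_graph.num_nodes
        assert small_graph.labels.min() >= 0
        assert small_graph.labels.max() < len(small_graph.label_names)

    def test_serialization_roundtrip(self, small_graph, tmp_path):
        small_graph.save(tmp_path)
        loaded = LearningGraph.load(tmp_path)
        assert np.array_equal(loaded.node_features, small_graph.node_features)
        assert np.array_equal(loaded.edges, small_graph.edges)
        assert np.array_equal(loaded.labels, small_graph.labels)
        assert np.array_equal(loaded.train_mask, small_graph.train_mask)
        assert loaded.encoders == small_graph.encoders
        assert loaded.label_names == small_graph.label_names
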