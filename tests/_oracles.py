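"""Independent oracles used by unit and acceptance tests.

These deliberately bypass the implementation paths they check: the
feature-table oracle joins parsed records in memory without touching
RDF; the edge oracle enumerates pairs brute-force; the metric oracle
counts by hand.
"""

from __future__ import annotations

import numpy as np

from variantkg.graph_build import NUMERIC_COLUMNS
from variantkg.rdfize import file_md5, info_key_canonical
from variantkg.store import FEATURE_COLUMNS
from variantkg.vcf_io import first_annotation

_INFO_COLUMN_FOR = {
    "ALLELE_COUNT": "allele_count",
    "ALLELE_FREQUENCY": "allele_frequency",
    "TOTAL_NUMBER_OF_ALLELES": "total_number_of_alleles",
    "BASEQRANKSUM": "baseqranksum",
    "DEPTH": "depth",
    "EXCESSHET": "excesshet",
    "FS": "fs",
    "MLEAC": "mleac",
    "MLEAF": "mleaf",
    "RMS_MAPPING_QUALITY": "RMS_mapping_quality",
    "QD": "qd",
    "READPOSRANKSUM": "readposranksum",
    "SOR": "sor",
}


def oracle_feature_table(bundle, cohort_dir) -> list[dict]:
    """Expected feature rows from direct in-memory joining of the parsed
    VCF/CADD/metadata records, with no RDF involved."""
    rows = []
    for patient in bundle.patients:
        digest = file_md5(cohort_dir / f"{patient.accession}.vcf")
        cadd_index = {
            (c.chrom, c.pos, c.ref, c.alt): (c.raw_score, c.phred)
            for c in patient.cadd
        }
        for i, rec in enumerate(patient.records):
            ann = rec.info.get("ANN", "")
            row = {c: "" for c in FEATURE_COLUMNS}
            row.update(
                accession_id=patient.accession,
                origin=f"origin://{digest}@{i}",
                variant_id=rec.variant_id or "None",
                chromosome=rec.chrom,
                position=str(rec.pos),
                ref_genome=rec.ref,
                alt_genome=rec.alt,
                quality=format(rec.qual, "g"),
                ann=ann,
                ann_split_1=first_annotation(ann),
                filter_status=rec.filter_status,
                genotype=rec.genotype or "",
                combined_depth="" if rec.combined_depth is None else str(rec.combined_depth),
                conditional_genotype_quality=""
                if rec.conditional_genotype_quality is None
                else str(rec.conditional_genotype_quality),
            )
            for key, value in rec.info.items():
                column = _INFO_COLUMN_FOR.get(info_key_canonical(key))
                if column is not None and value is not None:
                    row[column] = value
            scores = cadd_index.get((rec.chrom, rec.pos, rec.ref, rec.alt))
            if scores is not None:
                row["raw_score"], row["phred_score"] = f"{scores[0]:.6f}", f"{scores[1]:.2f}"
            rows.append(row)
    return rows


def assert_tables_equal(extracted, oracle_rows, tol: float = 1e-9) -> None:
    """Row-set comparison: strings bit-exact, numerics to ``tol``."""
    assert len(extracted) == len(oracle_rows)
    got = extracted.sort_values(["accession_id", "origin"]).reset_index(drop=True)
    expected = sorted(oracle_rows, key=lambda r: (r["accession_id"], r["origin"]))
    for i, exp in enumerate(expected):
        for col in FEATURE_COLUMNS:
            g, e = got.at[i, col], exp[col]
            if col in NUMERIC_COLUMNS:
                if e == "" or g == "":
                    assert g == e, f"row {i} col {col}: {g!r} != {e!r}"
                else:
                    assert abs(float(g) - float(e)) <= tol, f"row {i} col {col}: {g!r} != {e!r}"
            else:
                assert g == e, f"row {i} col {col}: {g!r} != {e!r}"


def oracle_gene_edges(genes: list[str], bidirectional: bool) -> set[tuple[int, int]]:
    """All node pairs sharing a nonempty gene, by brute-force enumeration."""
    edges = set()
    for i in range(len(genes)):
        for j in range(len(genes)):
            if i == j or not genes[i]:
                continue
            if genes[i] == genes[j] and (bidirectional or i < j):
                edges.add((i, j))
    return edges


def oracle_metrics(y_true: np.ndarray, y_pred: np.ndarray, num_classes: int) -> dict:
    """Counting-based accuracy/precision/recall/F1, independent of any
    metrics library."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    confusion = np.zeros((num_classes, num_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[t, p] += 1
    precision, recall, f1, support = [], [], [], []
    for c in range(num_classes):
        tp = confusion[c, c]
        fp = confusion[:, c].sum() - tp
        fn = confusion[c, :].sum() - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precision.append(p)
        recall.append(r)
        f1.append(2 * p * r / (p + r) if p + r else 0.0)
        support.append(confusion[c, :].sum())
    support = np.array(support)
    weights = support / support.sum() if support.sum() else np.zeros(num_classes)
    return {
        "accuracy": float((y_true == y_pred).mean()) if len(y_true) else 0.0,
        "precision": np.array(precision),
        "recall": np.array(recall),
        "f1": np.array(f1),
        "support": support,
        "macro_f1": float(np.mean(f1)),
        "weighted_f1": float(np.sum(np.array(f1) * weights)),
        "confusion": confusion,
    }


def oracle_khop(edges: np.ndarray, node_id: int, k: int) -> set[int]:
    """Breadth-first search over the undirected view, via networkx."""
    import networkx as nx

    g = nx.Graph()
    g.add_node(node_id)
    g.add_edges_from((int(s), int(d)) for s, d in edges if s != d)
    lengths = nx.single_source_shortest_path_length(g, node_id, cutoff=k)
    return set(lengths)
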