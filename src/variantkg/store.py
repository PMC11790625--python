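"""Embedded quad store and per-variant feature extraction.

An rdflib :class:`~rdflib.Dataset` plays the role of the graph database:
named graphs (one ``sg://<accession>`` graph per patient run) hold the
variant and metadata statements, while CADD score triples live in the
default graph.  ``extract_feature_table`` evaluates the feature
extraction query's plan directly over the dataset: per-origin mandatory
bindings (chromosome, position, REF, ALT, QUAL, ANN), OPTIONAL
INFO/FORMAT bindings left empty when absent, ``ann_split_1`` as the
first comma-separated annotation, and CADD raw/PHRED scores joined from
the default graph on (accession, position, ref, alt).  A SPARQL text
path over the same dataset is available for cross-checking on small
inputs.

Values are returned exactly as stored in the literals (decimal strings);
numeric typing happens later in graph construction.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from rdflib import Dataset, Graph, URIRef

from .rdfize import DEFAULT_PREDICATE_MAP, NS
from .vcf_io import first_annotation

__all__ = ["QuadStore", "FEATURE_COLUMNS"]

#: the selected variables of the extraction query, in SELECT order
FEATURE_COLUMNS = [
    "accession_id",
    "origin",
    "variant_id",
    "chromosome",
    "position",
    "ref_genome",
    "alt_genome",
    "quality",
    "ann",
    "ann_split_1",
    "filter_status",
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

_INFO_OPTIONALS = {
    "filter_status": "FILTER_STATUS",
    "allele_count": "ALLELE_COUNT",
    "allele_frequency": "ALLELE_FREQUENCY",
    "total_number_of_alleles": "TOTAL_NUMBER_OF_ALLELES",
    "baseqranksum": "BASEQRANKSUM",
    "depth": "DEPTH",
    "excesshet": "EXCESSHET",
    "fs": "FS",
    "mleac": "MLEAC",
    "mleaf": "MLEAF",
    "RMS_mapping_quality": "RMS_MAPPING_QUALITY",
    "qd": "QD",
    "readposranksum": "READPOSRANKSUM",
    "sor": "SOR",
    "combined_depth": "COMBINED_DEPTH",
    "conditional_genotype_quality": "CONDITIONAL_GENOTYPE_QUALITY",
    "genotype": "GENOTYPE",
    "raw_score": "RAW_SCORE",
    "phred_score": "PHRED_SCORE",
}

_FALDO_REF = URIRef(NS.faldo + "reference")
_FALDO_POS = URIRef(NS.faldo + "position")
_REF = URIRef(NS.vcf2rdf_variant + "REF")
_ALT = URIRef(NS.vcf2rdf_variant + "ALT")
_QUAL = URIRef(NS.vcf2rdf_variant + "QUAL")
_VARIANT_ID = URIRef(NS.vcf2rdf_variant + "variantId")
_ANN = URIRef(NS.vcf2rdf_info + "ANN")
_RDF_TYPE = URIRef(NS.rdf_type)
_SG_VARIANT = URIRef(NS.sgorg + "variant")
_HAS_POS = URIRef(NS.sgorg + "has_pos")
_HAS_REF = URIRef(NS.sgorg + "has_ref_genome")
_HAS_ALT = URIRef(NS.sgorg + "has_alt_genome")
_HAS_CADD = URIRef(NS.sgorg + "has_cadd_scores")
_HAS_RAW = URIRef(NS.sgorg + "has_raw_score")
_HAS_PHRED = URIRef(NS.sgorg + "has_phred")
_AGE_PRED = URIRef(DEFAULT_PREDICATE_MAP["age"])


class QuadStore:
    """In-process quad store over rdflib with named-graph support."""

    def __init__(self) -> None:
        self.ds = Dataset(default_union=False)

    # -- loading -----------------------------------------------------------

    def load(self, *paths: str | Path) -> dict[str, int]:
        """Load N-Quads (``.nq``) and Turtle (``.ttl``) files.

        Returns quad counts per named graph for the loaded files
        (key ``"default"`` for default-graph triples).  Loading the same
        file twice is idempotent (set semantics).
        """
        report: dict[str, int] = {}
        for path in paths:
            path = Path(path)
            fmt = "nquads" if path.suffix == ".nq" else "turtle"
            if fmt == "nquads":
                staging = Dataset(default_union=False)
                try:
                    staging.parse(str(path), format=fmt)
                except Exception as exc:  # rdflib reports position in message
                    raise ValueError(f"syntax error in {path}: {exc}") from exc
                for s, p, o, g in staging.quads((None, None, None, None)):
                    name = str(g) if g is not None else "default"
                    gid = g if g is not None else None
                    self.ds.add((s, p, o, gid))
                    report[name] = report.get(name, 0) + 1
            else:
                staging_g = Graph()
                try:
                    staging_g.parse(str(path), format=fmt)
                except Exception as exc:
                    raise ValueError(f"syntax error in {path}: {exc}") from exc
                default = self.ds.default_graph
                for s, p, o in staging_g:
                    default.add((s, p, o))
                report["default"] = report.get("default", 0) + len(staging_g)
        return report

    # -- cohort selection --------------------------------------------------

    def _named_graphs(self) -> list[str]:
        out = []
        for g in self.ds.graphs():
            name = str(g.identifier)
            if name.startswith("sg://"):
                out.append(name)
        return sorted(out)

    def list_accessions(self) -> list[str]:
        """Distinct accessions (named-graph IRIs minus ``sg://``), sorted."""
        return [g[len("sg://"):] for g in self._named_graphs()]

    def accessions_by_age(self, min_age: float, max_age: float) -> list[str]:
        """Accessions whose recorded patient age lies in [min_age, max_age];
        accessions without an age statement are excluded."""
        if min_age > max_age:
            raise ValueError("min_age must be <= max_age")
        selected = []
        for gname in self._named_graphs():
            g = self.ds.get_context(URIRef(gname))
            for _, _, age_lit in g.triples((None, _AGE_PRED, None)):
                try:
                    age = float(str(age_lit))
                except ValueError:
                    continue
                if min_age <= age <= max_age:
                    selected.append(gname[len("sg://"):])
                    break
        return selected

    # -- feature extraction ------------------------------------------------

    def _cadd_index(self) -> dict[tuple[str, str, str, str], tuple[str, str]]:
        """(accession, position, ref, alt) -> (raw_score, phred) from the
        default-graph CADD nodes."""
        default = self.ds.default_graph
        index: dict[tuple[str, str, str, str], tuple[str, str]] = {}
        for node in default.subjects(_RDF_TYPE, _SG_VARIANT):
            iri = str(node)
            if not iri.startswith(NS.sgorg):
                continue
            accession = iri[len(NS.sgorg):].split("/")[0]
            pos = default.value(node, _HAS_POS)
            ref = default.value(node, _HAS_REF)
            alt = default.value(node, _HAS_ALT)
            cadd = default.value(node, _HAS_CADD)
            if None in (pos, ref, alt, cadd):
                continue
            raw = default.value(cadd, _HAS_RAW)
            phred = default.value(cadd, _HAS_PHRED)
            index[(accession, str(pos), str(ref), str(alt))] = (
                "" if raw is None else str(raw),
                "" if phred is None else str(phred),
            )
        return index

    def extract_feature_table(
        self,
        accessions: list[str],
        features: list[str] | None = None,
        use_sparql: bool = False,
    ) -> pd.DataFrame:
        """Per-variant feature table for the given accessions.

        One row per (accession, origin) variant occurrence; optional
        bindings are empty strings when absent, ``variant_id`` is the
        string ``"None"`` when the VCF had no ID.  Rows are ordered by
        variant_id with (accession_id, origin) as deterministic
        tiebreaks.  ``features`` selects a subset of columns after
        evaluation.
        """
        if not accessions:
            raise ValueError("accessions must be nonempty")
        if features is not None:
            unknown = [f for f in features if f not in FEATURE_COLUMNS]
            if unknown:
                raise ValueError(
                    f"unknown feature(s) {unknown}; valid columns: {FEATURE_COLUMNS}"
                )
        if use_sparql:
            table = self._extract_sparql(accessions)
        else:
            table = self._extract_direct(accessions)
        table = table.sort_values(
            ["variant_id", "accession_id", "origin"], kind="mergesort"
        ).reset_index(drop=True)
        if features is not None:
            table = table[list(features)]
        return table

    def _extract_direct(self, accessions: list[str]) -> pd.DataFrame:
        cadd_index = self._cadd_index()
        rows: list[dict[str, str]] = []
        for accession in accessions:
            g = self.ds.get_context(URIRef(f"sg://{accession}"))
            origins = sorted({str(s) for s in g.subjects(_FALDO_POS, None)})
            for origin_iri in origins:
                origin = URIRef(origin_iri)
                ann = g.value(origin, _ANN)
                if ann is None:
                    continue  # ANN is a mandatory pattern in the query
                chrom = g.value(origin, _FALDO_REF)
                pos = g.value(origin, _FALDO_POS)
                ref = g.value(origin, _REF)
                alt = g.value(origin, _ALT)
                qual = g.value(origin, _QUAL)
                if None in (chrom, pos, ref, alt, qual):
                    continue
                vid = g.value(origin, _VARIANT_ID)
                ref_s = str(ref)[len(NS.vcf2rdf_seq):] if str(ref).startswith(NS.vcf2rdf_seq) else str(ref)
                alt_s = str(alt)[len(NS.vcf2rdf_seq):] if str(alt).startswith(NS.vcf2rdf_seq) else str(alt)
                row = {
                    "accession_id": accession,
                    "origin": origin_iri,
                    "variant_id": "None" if vid is None else str(vid),
                    "chromosome": str(chrom),
                    "position": str(pos),
                    "ref_genome": ref_s,
                    "alt_genome": alt_s,
                    "quality": str(qual),
                    "ann": str(ann),
                    "ann_split_1": first_annotation(str(ann)),
                }
                for col, local in _INFO_OPTIONALS.items():
                    val = g.value(origin, URIRef(NS.vcf2rdf_info + local))
                    row[col] = "" if val is None else str(val)
                if not row["raw_score"] or not row["phred_score"]:
                    joined = cadd_index.get((accession, str(pos), ref_s, alt_s))
                    if joined is not None:
                        row["raw_score"] = row["raw_score"] or joined[0]
                        row["phred_score"] = row["phred_score"] or joined[1]
                rows.append(row)
        table = pd.DataFrame(rows, columns=FEATURE_COLUMNS, dtype=object)
        return table.drop_duplicates().reset_index(drop=True)

    def feature_query_text(self, accessions: list[str]) -> str:
        """The extraction query as SPARQL text.

        The CADD join block matches on (accession, position, ref base,
        alt base) with the sequence-namespace tail stripped from the
        REF/ALT IRIs — the documented intent of the trailing join.
        """
        acc_list = ", ".join(f"<sg://{a}>" for a in accessions)
        optionals = "\n".join(
            f"      OPTIONAL {{ ?origin sg_info:{local} ?{col} . }}"
            for col, local in _INFO_OPTIONALS.items()
        )
        return f"""
    PREFIX sg_biohackathon: <{NS.faldo}>
    PREFIX sg_variant: <{NS.vcf2rdf_variant}>
    PREFIX sg_info: <{NS.vcf2rdf_info}>
    PREFIX ns1: <{NS.sgorg}>
    SELECT DISTINCT ?accession_id ?origin
           (COALESCE(?variant_id_raw, "None") AS ?variant_id)
           ?chromosome ?position ?ref_genome ?alt_genome ?quality ?ann
           ?ann_split_1 ?filter_status ?allele_count ?allele_frequency
           ?total_number_of_alleles ?baseqranksum ?depth ?excesshet ?fs
           ?mleac ?mleaf ?RMS_mapping_quality ?qd ?readposranksum ?sor
           ?combined_depth ?conditional_genotype_quality ?genotype
           (COALESCE(?raw_score, ?cadd_raw) AS ?raw_score_out)
           (COALESCE(?phred_score, ?cadd_phred) AS ?phred_score_out)
    WHERE {{
      GRAPH ?accession_id {{
        OPTIONAL {{ ?origin sg_variant:variantId ?variant_id_raw . }}
        ?origin sg_biohackathon:reference ?chromosome .
        ?origin sg_biohackathon:position ?position .
        ?origin sg_variant:REF ?ref_genome .
        ?origin sg_variant:ALT ?alt_genome .
        ?origin sg_variant:QUAL ?quality .
        ?origin sg_info:ANN ?ann .
        BIND (IF(STRLEN(?ann) - STRLEN(REPLACE(?ann, ",", "")) = 0,
                 ?ann, STRBEFORE(?ann, ",")) AS ?ann_split_1)
{optionals}
      }}
      BIND (STRAFTER(STR(?ref_genome), "sequence/") AS ?ref_base)
      BIND (STRAFTER(STR(?alt_genome), "sequence/") AS ?alt_base)
      OPTIONAL {{
        ?variant ns1:has_pos ?position ;
                 ns1:has_ref_genome ?ref_base ;
                 ns1:has_alt_genome ?alt_base ;
                 ns1:has_cadd_scores ?cadd_scores .
        FILTER (STRSTARTS(STR(?variant),
                CONCAT("{NS.sgorg}", STRAFTER(STR(?accession_id), "sg://"), "/")))
        OPTIONAL {{ ?cadd_scores ns1:has_raw_score ?cadd_raw . }}
        OPTIONAL {{ ?cadd_scores ns1:has_phred ?cadd_phred . }}
      }}
      FILTER (?accession_id IN ({acc_list}))
    }} ORDER BY ?variant_id
    """

    def _extract_sparql(self, accessions: list[str]) -> pd.DataFrame:
        results = self.ds.query(self.feature_query_text(accessions))
        rows = []
        rename = {"raw_score_out": "raw_score", "phred_score_out": "phred_score"}
        for binding in results:
            asdict = binding.asdict()
            row = {}
            for var, value in asdict.items():
                col = rename.get(str(var), str(var))
                if col == "accession_id":
                    row[col] = str(value)[len("sg://"):]
                elif col in ("ref_genome", "alt_genome"):
                    s = str(value)
                    row[col] = s[len(NS.vcf2rdf_seq):] if s.startswith(NS.vcf2rdf_seq) else s
                else:
                    row[col] = str(value)
            for col in FEATURE_COLUMNS:
                row.setdefault(col, "")
            rows.append(row)
        table = pd.DataFrame(rows, columns=FEATURE_COLUMNS, dtype=object)
        return table.drop_duplicates().reset_index(drop=True)

    def write_feature_table(self, table: pd.DataFrame, path: str | Path) -> None:
        """Persist an extracted table as CSV (and Parquet when the path
        ends in ``.parquet``) for the graph builder."""
        path = Path(path)
        if path.suffix == ".parquet":
            table.to_parquet(path)
        else:
            table.to_csv(path, index=False)
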