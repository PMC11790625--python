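"""RDF emission for variants, CADD scores, and patient metadata.

Each patient (SRA run accession) gets a named graph ``sg://<accession>``
holding the variant statements converted from their VCF plus their
metadata statements; variant subjects are ``origin://<md5>@<index>``
IRIs derived from the source file digest and the 0-based data-line
index.  CADD scores live in the default graph as Turtle, with one
``http://sg.org/<accession>/<chrom>/variant<k>`` node per score row and
a child ``.../cadd`` node carrying ``has_raw_score`` / ``has_phred``.
Positions use the FALDO vocabulary (``faldo:reference``,
``faldo:position``); all other variant-level predicates follow the
``sg://0.99.11/vcf2rdf/`` namespaces so the downstream feature
extraction query resolves against this output unmodified.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

from .vcf_io import CaddRow, PatientMetadata, VariantRecord, parse_cadd_tsv, parse_vcf

__all__ = [
    "Term",
    "Quad",
    "NS",
    "XSD",
    "make_origin_uri",
    "variant_to_quads",
    "info_key_canonical",
    "cadd_to_triples",
    "metadata_to_quads",
    "rdfize_cohort",
    "serialize_nquads",
    "serialize_turtle",
    "DEFAULT_PREDICATE_MAP",
]


class NS:
    """Fixed ontology namespaces (the vcf2rdf version segment 0.99.11 is
    hard-coded by the consuming extraction query and must not change)."""

    faldo = "http://biohackathon.org/resource/faldo#"
    vcf2rdf_base = "sg://0.99.11/vcf2rdf/"
    vcf2rdf_variant = "sg://0.99.11/vcf2rdf/variant/"
    vcf2rdf_info = "sg://0.99.11/vcf2rdf/info/"
    vcf2rdf_seq = "sg://0.99.11/vcf2rdf/sequence/"
    sgorg = "http://sg.org/"
    sra = "https://www.ncbi.nlm.nih.gov/sra/?term="
    wikidata = "https://www.wikidata.org/wiki/"
    rdf_type = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"


class XSD:
    integer = "http://www.w3.org/2001/XMLSchema#integer"
    float = "http://www.w3.org/2001/XMLSchema#float"
    string = "http://www.w3.org/2001/XMLSchema#string"
    boolean = "http://www.w3.org/2001/XMLSchema#boolean"


@dataclass(frozen=True)
class Term:
    kind: str  # "iri" | "literal"
    value: str
    datatype: str | None = None

    @staticmethod
    def iri(value: str) -> "Term":
        return Term("iri", value)

    @staticmethod
    def literal(value: str, datatype: str = XSD.string) -> "Term":
        return Term("literal", value, datatype)


@dataclass(frozen=True)
class Quad:
    subject: Term
    predicate: Term
    object: Term
    graph: Term | None = None  # absent = default graph (Turtle output)


def make_origin_uri(file_digest: str, record_index: int) -> Term:
    """Build the ``origin://<digest>@<index>`` subject IRI for a variant."""
    if len(file_digest) != 32 or not all(c in "0123456789abcdef" for c in file_digest):
        raise ValueError(f"file digest must be 32 lowercase hex chars, got {file_digest!r}")
    if record_index < 0:
        raise ValueError("record index must be non-negative")
    return Term.iri(f"origin://{file_digest}@{record_index}")


_INFO_KEY_MAP = {
    "AC": "ALLELE_COUNT",
    "AF": "ALLELE_FREQUENCY",
    "AN": "TOTAL_NUMBER_OF_ALLELES",
    "BaseQRankSum": "BASEQRANKSUM",
    "DP": "DEPTH",
    "ExcessHet": "EXCESSHET",
    "FS": "FS",
    "MLEAC": "MLEAC",
    "MLEAF": "MLEAF",
    "MQ": "RMS_MAPPING_QUALITY",
    "QD": "QD",
    "ReadPosRankSum": "READPOSRANKSUM",
    "SOR": "SOR",
    "ANN": "ANN",
}


def info_key_canonical(vcf_key: str) -> str:
    """Canonical predicate local name for a VCF INFO key (unknown keys
    pass through upper-cased)."""
    return _INFO_KEY_MAP.get(vcf_key, vcf_key.upper())


def variant_to_quads(record: VariantRecord, origin: Term, accession: str) -> list[Quad]:
    """Convert one variant record into its named-graph statements."""
    if not accession:
        raise ValueError("accession must be nonempty")
    g = Term.iri(f"sg://{accession}")
    quads = [
        Quad(origin, Term.iri(NS.faldo + "reference"), Term.literal(record.chrom), g),
        Quad(
            origin,
            Term.iri(NS.faldo + "position"),
            Term.literal(str(record.pos), XSD.integer),
            g,
        ),
        Quad(origin, Term.iri(NS.vcf2rdf_variant + "REF"), Term.iri(NS.vcf2rdf_seq + record.ref), g),
        Quad(origin, Term.iri(NS.vcf2rdf_variant + "ALT"), Term.iri(NS.vcf2rdf_seq + record.alt), g),
        Quad(
            origin,
            Term.iri(NS.vcf2rdf_variant + "QUAL"),
            Term.literal("" if record.qual is None else format(record.qual, "g"), XSD.float),
            g,
        ),
        Quad(
            origin,
            Term.iri(NS.vcf2rdf_info + "FILTER_STATUS"),
            Term.literal(record.filter_status),
            g,
        ),
    ]
    if record.variant_id is not None:
        quads.insert(
            4,
            Quad(origin, Term.iri(NS.vcf2rdf_variant + "variantId"), Term.literal(record.variant_id), g),
        )
    for key, value in record.info.items():
        obj = (
            Term.literal("true", XSD.boolean)
            if value is None
            else Term.literal(value)
        )
        quads.append(Quad(origin, Term.iri(NS.vcf2rdf_info + info_key_canonical(key)), obj, g))
    if record.genotype is not None:
        quads.append(
            Quad(origin, Term.iri(NS.vcf2rdf_info + "GENOTYPE"), Term.literal(record.genotype), g)
        )
    if record.combined_depth is not None:
        quads.append(
            Quad(
                origin,
                Term.iri(NS.vcf2rdf_info + "COMBINED_DEPTH"),
                Term.literal(str(record.combined_depth), XSD.integer),
                g,
            )
        )
    if record.conditional_genotype_quality is not None:
        quads.append(
            Quad(
                origin,
                Term.iri(NS.vcf2rdf_info + "CONDITIONAL_GENOTYPE_QUALITY"),
                Term.literal(str(record.conditional_genotype_quality), XSD.integer),
                g,
            )
        )
    return quads


def _format_float(x: float) -> str:
    # keep 61.0 as "61.0" but 0.900784 as "0.900784"
    s = repr(float(x))
    return s


def cadd_to_triples(row: CaddRow, accession: str, per_chrom_index: int) -> list[Quad]:
    """Convert one CADD score row into default-graph Turtle triples.

    ``per_chrom_index`` is the 1-based order of the row within
    (accession, chromosome), forming node IRIs like
    ``http://sg.org/SRR13112995/1/variant1``.
    """
    if per_chrom_index < 1:
        raise ValueError("per_chrom_index is 1-based")
    node = Term.iri(f"{NS.sgorg}{accession}/{row.chrom}/variant{per_chrom_index}")
    cadd = Term.iri(node.value + "/cadd")
    return [
        Quad(node, Term.iri(NS.rdf_type), Term.iri(NS.sgorg + "variant")),
        Quad(node, Term.iri(NS.sgorg + "has_pos"), Term.literal(str(row.pos), XSD.integer)),
        Quad(node, Term.iri(NS.sgorg + "has_ref_genome"), Term.literal(row.ref)),
        Quad(node, Term.iri(NS.sgorg + "has_alt_genome"), Term.literal(row.alt)),
        Quad(node, Term.iri(NS.sgorg + "has_cadd_scores"), cadd),
        Quad(cadd, Term.iri(NS.sgorg + "has_raw_score"), Term.literal(_format_float(row.raw_score), XSD.float)),
        Quad(cadd, Term.iri(NS.sgorg + "has_phred"), Term.literal(_format_float(row.phred), XSD.float)),
    ]


#: field -> Wikidata predicate IRI; only the age concept is pinned by the
#: ontology, the rest are editable placeholders.
DEFAULT_PREDICATE_MAP = {
    "age": NS.wikidata + "Q11904283",
    "sex": NS.wikidata + "Q290",
    "disease_stage": NS.wikidata + "Q112193867",
    "tissue": NS.wikidata + "Q40397",
}


def metadata_to_quads(
    patient: PatientMetadata, predicate_map: dict[str, str] | None = None
) -> list[Quad]:
    """Convert patient metadata into named-graph statements keyed by the
    SRA accession IRI; unmapped fields are skipped with a warning."""
    pmap = DEFAULT_PREDICATE_MAP if predicate_map is None else predicate_map
    if "age" not in pmap:
        raise ValueError("predicate_map must at least map 'age'")
    subject = Term.iri(NS.sra + patient.accession)
    g = Term.iri(f"sg://{patient.accession}")
    quads: list[Quad] = []
    fields: list[tuple[str, str | None, str | None]] = [
        ("age", None if patient.age is None else _format_float(patient.age), XSD.float),
        ("sex", patient.sex, XSD.string),
        ("disease_stage", patient.disease_stage, XSD.string),
        ("tissue", patient.tissue, XSD.string),
    ]
    for name, value, dtype in fields:
        if value is None:
            continue
        if name not in pmap:
            warnings.warn(f"metadata field {name!r} has no predicate mapping; skipped")
            continue
        quads.append(Quad(subject, Term.iri(pmap[name]), Term.literal(value, dtype), g))
    return quads


# --- serialization ---------------------------------------------------------

_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}


def _escape(value: str) -> str:
    return "".join(_ESCAPES.get(c, c) for c in value)


def _term_nt(term: Term) -> str:
    if term.kind == "iri":
        return f"<{term.value}>"
    lit = f'"{_escape(term.value)}"'
    if term.datatype and term.datatype != XSD.string:
        lit += f"^^<{term.datatype}>"
    return lit


def serialize_nquads(quads: list[Quad]) -> str:
    """Write quads as N-Quads text, one statement per line, in order."""
    lines = []
    for q in quads:
        parts = [_term_nt(q.subject), _term_nt(q.predicate), _term_nt(q.object)]
        if q.graph is not None:
            parts.append(_term_nt(q.graph))
        lines.append(" ".join(parts) + " .")
    return "\n".join(lines) + ("\n" if lines else "")


def serialize_turtle(quads: list[Quad]) -> str:
    """Write default-graph triples as Turtle, grouped by subject."""
    header = f"@prefix ns1: <{NS.sgorg}> .\n\n"
    by_subject: dict[str, list[Quad]] = {}
    order: list[str] = []
    for q in quads:
        if q.subject.value not in by_subject:
            order.append(q.subject.value)
        by_subject.setdefault(q.subject.value, []).append(q)

    def _ttl_term(term: Term) -> str:
        if term.kind == "iri":
            if term.value.startswith(NS.sgorg):
                tail = term.value[len(NS.sgorg):]
                if tail and all(c.isalnum() or c in "_" for c in tail):
                    return f"ns1:{tail}"
            return f"<{term.value}>"
        if term.datatype == XSD.integer:
            return term.value
        if term.datatype == XSD.float:
            lit = f'"{_escape(term.value)}"'
            return f"{lit}^^<{XSD.float}>"
        return f'"{_escape(term.value)}"'

    blocks = []
    for subj in order:
        qs = by_subject[subj]
        lines = [f"<{subj}>"]
        preds = []
        for q in qs:
            if q.predicate.value == NS.rdf_type:
                preds.append(f"    a {_ttl_term(q.object)}")
            else:
                preds.append(f"    {_ttl_term(q.predicate)} {_ttl_term(q.object)}")
        blocks.append("<%s> %s .\n" % (subj, " ;\n".join(p.strip() if i == 0 else p for i, p in enumerate(preds))))
    return header + "\n".join(blocks)


# --- cohort driver ---------------------------------------------------------


def _accession_from_path(path: Path) -> str:
    stem = path.name
    for suffix in (".vcf", ".tsv", ".csv"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    return stem.split(".")[0]


def file_md5(path: Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def rdfize_cohort(
    vcf_paths: list[str | Path],
    cadd_paths: list[str | Path],
    metadata_path: str | Path | None,
    out_dir: str | Path,
    workers: int = 1,
) -> dict:
    """Convert a cohort's VCF/CADD/metadata files into per-accession
    N-Quads files, one CADD Turtle file, and a manifest.

    Per-file conversion is stateless, so output bytes are identical
    regardless of processing order or ``workers``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    vcf_by_acc: dict[str, Path] = {}
    for p in map(Path, vcf_paths):
        acc = _accession_from_path(p)
        if acc in vcf_by_acc:
            raise ValueError(f"accession collision: {acc!r} appears in multiple VCFs")
        vcf_by_acc[acc] = p
    cadd_by_acc = {_accession_from_path(Path(p)): Path(p) for p in cadd_paths}

    meta_by_acc: dict[str, PatientMetadata] = {}
    if metadata_path is not None:
        from .vcf_io import parse_metadata_csv

        with open(metadata_path) as fh:
            for patient in parse_metadata_csv(fh):
                meta_by_acc[patient.accession] = patient

    def _convert_one(acc: str) -> str:
        path = vcf_by_acc[acc]
        digest = file_md5(path)
        with open(path) as fh:
            _, records = parse_vcf(fh, split_multiallelic=True)
        quads: list[Quad] = []
        for idx, rec in enumerate(records):
            quads.extend(variant_to_quads(rec, make_origin_uri(digest, idx), acc))
        if acc in meta_by_acc:
            quads.extend(metadata_to_quads(meta_by_acc[acc]))
        return serialize_nquads(quads)

    accessions = sorted(vcf_by_acc)
    if workers > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=workers) as pool:
            texts = dict(zip(accessions, pool.map(_convert_one, accessions)))
    else:
        texts = {acc: _convert_one(acc) for acc in accessions}

    nq_files = {}
    for acc in accessions:
        nq_path = out / f"{acc}.nq"
        nq_path.write_text(texts[acc])
        nq_files[acc] = nq_path.name

    cadd_quads: list[Quad] = []
    for acc in sorted(cadd_by_acc):
        with open(cadd_by_acc[acc]) as fh:
            rows = parse_cadd_tsv(fh)
        counters: dict[str, int] = {}
        for row in rows:
            counters[row.chrom] = counters.get(row.chrom, 0) + 1
            cadd_quads.extend(cadd_to_triples(row, acc, counters[row.chrom]))
    ttl_path = out / "cadd.ttl"
    ttl_path.write_text(serialize_turtle(cadd_quads))

    manifest = {
        "accessions": {
            acc: {
                "nq": nq_files[acc],
                "cadd": "cadd.ttl" if acc in cadd_by_acc else None,
            }
            for acc in accessions
        },
        "turtle": ttl_path.name,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
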