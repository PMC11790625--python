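"""Parsers for the three tabular inputs of the pipeline.

Three file families feed the knowledge graph: VCF 4.x files whose INFO
field carries SnpEff ``ANN`` functional annotations, CADD score tables
(tab-separated, ``#Chrom Pos Ref Alt RawScore PHRED``), and patient
metadata tables in the SRA RunInfo CSV dialect.  Everything is parsed
from text streams into plain dataclasses; no coordinate system other
than 1-based VCF positions is used anywhere.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

__all__ = [
    "VariantRecord",
    "AnnAnnotation",
    "CaddRow",
    "PatientMetadata",
    "VcfParseError",
    "ConfigurationError",
    "parse_vcf",
    "parse_ann",
    "first_annotation",
    "parse_cadd_tsv",
    "parse_metadata_csv",
    "serialize_vcf_fields",
]

_VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y", "MT"}


class VcfParseError(ValueError):
    """Malformed line in a VCF / CADD / metadata input."""


class ConfigurationError(ValueError):
    """The caller-supplied configuration (e.g. column map) is unusable."""


@dataclass
class VariantRecord:
    """One VCF data line after optional multi-allelic splitting.

    ``info`` preserves the file order of INFO keys; flag keys (present
    without ``=``) map to ``None``.  Sample-level GT/DP/GQ from the first
    sample column are lifted into dedicated fields when present.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str | None = None
    qual: float | None = None
    filter_status: str = "."
    info: dict[str, str | None] = field(default_factory=dict)
    genotype: str | None = None
    combined_depth: int | None = None
    conditional_genotype_quality: int | None = None


@dataclass
class AnnAnnotation:
    """One pipe-separated SnpEff ANN token, split positionally.

    The first nine subfields get names (allele, effect, putative impact,
    gene name, gene ID, feature type, feature ID, transcript biotype,
    rank); everything after stays in ``remainder`` (HGVS notations,
    positions, distances, warnings).  ``to_token`` reproduces the source
    token exactly, including its original field count.
    """

    allele: str
    effect: str
    putative_impact: str
    gene_name: str
    gene_id: str = ""
    feature_type: str = ""
    feature_id: str = ""
    transcript_biotype: str = ""
    rank: str = ""
    remainder: list[str] = field(default_factory=list)
    _n_fields: int = 0

    _NAMED = (
        "allele",
        "effect",
        "putative_impact",
        "gene_name",
        "gene_id",
        "feature_type",
        "feature_id",
        "transcript_biotype",
        "rank",
    )

    def to_token(self) -> str:
        parts = [getattr(self, name) for name in self._NAMED] + list(self.remainder)
        n = self._n_fields or len(parts)
        return "|".join(parts[:n])


@dataclass
class CaddRow:
    """One row of a CADD score table (raw model score + PHRED-scaled)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    raw_score: float
    phred: float


@dataclass
class PatientMetadata:
    """Per-run patient attributes keyed by the SRA run accession."""

    accession: str
    age: float | None = None
    sex: str | None = None
    disease_stage: str | None = None
    tissue: str | None = None
    extra: dict[str, str] = field(default_factory=dict)


def _parse_info(info_field: str) -> dict[str, str | None]:
    info: dict[str, str | None] = {}
    if info_field in (".", ""):
        return info
    for item in info_field.split(";"):
        if not item:
            continue
        if "=" in item:
            key, _, value = item.partition("=")
            info[key] = value
        else:
            info[item] = None  # flag
    return info


def serialize_vcf_fields(record: VariantRecord) -> str:
    """Rebuild the first eight tab-separated VCF columns of a record."""
    info_items = []
    for key, value in record.info.items():
        info_items.append(key if value is None else f"{key}={value}")
    return "\t".join(
        [
            record.chrom,
            str(record.pos),
            record.variant_id if record.variant_id is not None else ".",
            record.ref,
            record.alt,
            "." if record.qual is None else format(record.qual, "g"),
            record.filter_status,
            ";".join(info_items) if info_items else ".",
        ]
    )


def parse_vcf(
    stream: IO[str] | Iterable[str], split_multiallelic: bool = False
) -> tuple[list[str], list[VariantRecord]]:
    """Parse a VCF 4.x text stream into header lines and variant records.

    With ``split_multiallelic`` a line whose ALT holds comma-separated
    alleles yields one record per alternate allele, in order, each
    carrying the full INFO map (per-allele INFO values are not
    re-apportioned).  Without it such a line raises, instructing the
    caller to enable splitting.
    """
    header: list[str] = []
    records: list[VariantRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line:
            continue
        if line.startswith("#"):
            header.append(line)
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise VcfParseError(
                f"line {lineno}: expected >= 8 tab-separated columns, got {len(cols)}"
            )
        chrom, pos_s, vid, ref, alt_field, qual_s, filt, info_s = cols[:8]
        try:
            pos = int(pos_s)
        except ValueError:
            raise VcfParseError(f"line {lineno}: non-integer POS {pos_s!r}") from None
        if pos < 1:
            raise VcfParseError(f"line {lineno}: POS must be >= 1, got {pos}")
        qual = None if qual_s in (".", "") else float(qual_s)
        if qual is not None and qual < 0:
            raise VcfParseError(f"line {lineno}: negative QUAL {qual}")
        info = _parse_info(info_s)

        genotype = combined_depth = gq = None
        if len(cols) >= 10:
            fmt_keys = cols[8].split(":")
            sample_vals = cols[9].split(":")
            sample = dict(zip(fmt_keys, sample_vals))
            genotype = sample.get("GT")
            if sample.get("DP") not in (None, "."):
                combined_depth = int(sample["DP"])
            if sample.get("GQ") not in (None, "."):
                gq = int(sample["GQ"])

        alts = alt_field.split(",")
        if len(alts) > 1 and not split_multiallelic:
            raise VcfParseError(
                f"line {lineno}: multi-allelic ALT {alt_field!r}; "
                "enable split_multiallelic to split into per-allele records"
            )
        for alt in alts:
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    variant_id=None if vid == "." else vid,
                    ref=ref,
                    alt=alt,
                    qual=qual,
                    filter_status=filt,
                    info=dict(info),
                    genotype=genotype,
                    combined_depth=combined_depth,
                    conditional_genotype_quality=gq,
                )
            )
    return header, records


def parse_ann(ann_token: str) -> AnnAnnotation:
    """Split one SnpEff ANN token on ``|`` into its positional fields."""
    fields = ann_token.split("|")
    if len(fields) < 4:
        raise VcfParseError(
            f"ANN token needs >= 4 pipe-separated fields, got {len(fields)}: {ann_token!r}"
        )
    padded = fields + [""] * max(0, 9 - len(fields))
    return AnnAnnotation(
        allele=padded[0],
        effect=padded[1],
        putative_impact=padded[2],
        gene_name=padded[3],
        gene_id=padded[4],
        feature_type=padded[5],
        feature_id=padded[6],
        transcript_biotype=padded[7],
        rank=padded[8],
        remainder=fields[9:],
        _n_fields=len(fields),
    )


def first_annotation(ann_value: str) -> str:
    """Return the first comma-separated annotation of an ANN value.

    Mirrors the extraction query's BIND: a value with no comma is
    returned unchanged, otherwise the substring before the first comma.
    """
    if "," not in ann_value:
        return ann_value
    return ann_value.split(",", 1)[0]


def parse_cadd_tsv(stream: IO[str] | Iterable[str]) -> list[CaddRow]:
    """Parse a CADD score table (``#Chrom Pos Ref Alt RawScore PHRED``)."""
    rows: list[CaddRow] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 6:
            raise VcfParseError(f"line {lineno}: expected 6 columns, got {len(cols)}")
        chrom, pos_s, ref, alt, raw_s, phred_s = cols
        try:
            pos = int(pos_s)
            raw_score = float(raw_s)
            phred = float(phred_s)
        except ValueError:
            raise VcfParseError(f"line {lineno}: non-numeric field in {cols!r}") from None
        if pos < 1:
            raise VcfParseError(f"line {lineno}: Pos must be >= 1, got {pos}")
        rows.append(CaddRow(chrom, pos, ref, alt, raw_score, phred))
    return rows


_LEADING_NUMBER = re.compile(r"\s*([-+]?\d+(?:\.\d+)?)")

#: default logical-field -> column-name map for SRA RunInfo style tables
DEFAULT_COLUMN_MAP = {
    "accession": "Run",
    "age": "Age",
    "sex": "sex",
    "disease_stage": "disease_stage",
    "tissue": "tissue",
}


def parse_metadata_csv(
    stream: IO[str] | Iterable[str], column_map: dict[str, str] | None = None
) -> list[PatientMetadata]:
    """Parse a patient metadata CSV keyed by run accession.

    ``column_map`` maps the logical fields (accession, age, sex,
    disease_stage, tissue) to column names in the file.  Age cells may be
    decorated like ``"65 (Age)"``; the leading number is extracted.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    reader = csv.DictReader(stream)
    if reader.fieldnames is None or cmap["accession"] not in reader.fieldnames:
        raise ConfigurationError(
            f"metadata CSV lacks accession column {cmap['accession']!r}; "
            f"columns present: {reader.fieldnames}"
        )
    known_cols = {v for v in cmap.values() if v}
    patients: list[PatientMetadata] = []
    seen: set[str] = set()
    for row in reader:
        accession = (row.get(cmap["accession"]) or "").strip()
        if not accession:
            raise VcfParseError("metadata row with empty accession")
        if accession in seen:
            raise VcfParseError(f"duplicate accession {accession!r} in metadata")
        seen.add(accession)

        age = None
        age_cell = row.get(cmap.get("age", ""), "") or ""
        m = _LEADING_NUMBER.match(age_cell)
        if m:
            age = float(m.group(1))

        def _opt(field_name: str) -> str | None:
            cell = row.get(cmap.get(field_name, ""), "") or ""
            cell = cell.strip()
            return cell or None

        extra = {
            k: v for k, v in row.items() if k is not None and k not in known_cols and v
        }
        patients.append(
            PatientMetadata(
                accession=accession,
                age=age,
                sex=_opt("sex"),
                disease_stage=_opt("disease_stage"),
                tissue=_opt("tissue"),
                extra=extra,
            )
        )
    return patients
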