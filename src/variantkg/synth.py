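"""Deterministic synthetic cohorts for end-to-end testing and benchmarks.

The generator emulates the output of an upstream variant-calling +
SnpEff annotation pipeline for a multi-patient cohort: per patient one
annotated VCF (INFO carries an ANN token), one CADD score table aligned
to the VCF records, and one shared metadata CSV.  What it plants, and
how strongly, is controlled by ``signal_strength`` in [0, 1]:

* each variant's putative-impact class is drawn from ``class_priors``;
* gene choice is class-tilted: each impact class prefers its own quarter
  of the gene pool with probability ``signal_strength`` (deleterious
  variants cluster in disease genes), so gene-clique neighborhoods carry
  label signal and graph aggregation has something to learn from;
* the PHRED-scaled CADD score is drawn from a class-conditional normal
  whose class means spread across the 0-40 range as the signal grows
  (at 0 all classes share one distribution);
* one designated INFO feature (``QD``, quality by depth) is
  class-informative at the same strength; all remaining INFO fields are
  class-independent noise in plausible ranges.

A fixed seed yields byte-identical files.  The cohort is *statistically*
plausible, not biologically realistic: no linkage structure, no real
mutation spectrum, and CADD scores come from the planted model rather
than the real CADD pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .vcf_io import CaddRow, PatientMetadata, VariantRecord

__all__ = ["CohortSpec", "PatientData", "CohortBundle", "generate_cohort", "write_cohort"]

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")

#: SnpEff effect terms consistent with each impact tier
_EFFECTS = {
    "HIGH": ("stop_gained", "frameshift_variant", "splice_donor_variant"),
    "MODERATE": ("missense_variant", "inframe_deletion"),
    "LOW": ("synonymous_variant", "splice_region_variant"),
    "MODIFIER": ("intergenic_region", "intron_variant", "downstream_gene_variant"),
}

# class-conditional means at full signal, spread over the PHRED 0-40 range
_PHRED_MEANS = {"MODIFIER": 4.0, "LOW": 13.0, "MODERATE": 23.0, "HIGH": 33.0}
_PHRED_SD = 3.0
_PHRED_GLOBAL_MEAN = 17.0

# designated class-informative INFO feature: QD (quality by depth)
_QD_MEANS = {"MODIFIER": 4.0, "LOW": 12.0, "MODERATE": 22.0, "HIGH": 30.0}
_QD_SD = 2.5
_QD_GLOBAL_MEAN = 16.0

DESIGNATED_FEATURE = "qd"

_BASES = ("A", "C", "G", "T")


@dataclass
class CohortSpec:
    n_patients: int = 20
    variants_per_patient: int = 200
    gene_pool: list[str] = field(
        default_factory=lambda: [f"GENE{i:03d}" for i in range(1, 25)]
    )
    class_priors: dict[str, float] = field(
        default_factory=lambda: {
            "HIGH": 0.15,
            "MODERATE": 0.35,
            "LOW": 0.25,
            "MODIFIER": 0.25,
        }
    )
    signal_strength: float = 0.9
    age_range: tuple[float, float] = (20.0, 90.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.gene_pool:
            raise ValueError("gene_pool must be nonempty")
        total = sum(self.class_priors.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_priors must sum to 1, got {total}")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")


@dataclass
class PatientData:
    accession: str
    records: list[VariantRecord]
    cadd: list[CaddRow]
    metadata: PatientMetadata
    impacts: list[str]  # ground-truth class per record, aligned


@dataclass
class CohortBundle:
    spec: CohortSpec
    patients: list[PatientData]


def _fmt(x: float, nd: int) -> str:
    return f"{x:.{nd}f}"


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Draw a full cohort from the spec's planted model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = spec.signal_strength
    classes = list(spec.class_priors)
    priors = np.array([spec.class_priors[c] for c in classes])

    # class-preferred gene subsets: round-robin quarters of the pool
    gene_groups = {
        c: [g for i, g in enumerate(spec.gene_pool) if i % len(classes) == ci]
        or list(spec.gene_pool)
        for ci, c in enumerate(classes)
    }

    patients: list[PatientData] = []
    for p in range(spec.n_patients):
        accession = f"SRR{90000000 + p:08d}"
        n = spec.variants_per_patient
        # positions: unique per (chrom), sorted for VCF validity
        chroms = rng.integers(1, 23, size=n)
        positions = rng.integers(10_000, 50_000_000, size=n)
        order = np.lexsort((positions, chroms))
        chroms, positions = chroms[order], positions[order]

        impacts = [classes[i] for i in rng.choice(len(classes), size=n, p=priors)]
        records: list[VariantRecord] = []
        cadd_rows: list[CaddRow] = []
        for i in range(n):
            impact = impacts[i]
            chrom = str(chroms[i])
            pos = int(positions[i])
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            if rng.random() < s:
                group = gene_groups[impact]
                gene = group[int(rng.integers(len(group)))]
            else:
                gene = spec.gene_pool[int(rng.integers(len(spec.gene_pool)))]
            gene_idx = spec.gene_pool.index(gene)
            effect = _EFFECTS[impact][int(rng.integers(len(_EFFECTS[impact])))]

            phred_mean = (1 - s) * _PHRED_GLOBAL_MEAN + s * _PHRED_MEANS[impact]
            phred = max(0.01, float(rng.normal(phred_mean, _PHRED_SD)))
            raw = float((phred - 15.0) / 10.0 + rng.normal(0.0, 0.05))

            qd_mean = (1 - s) * _QD_GLOBAL_MEAN + s * _QD_MEANS[impact]
            qd = max(0.01, float(rng.normal(qd_mean, _QD_SD)))

            ac = int(rng.integers(1, 3))
            af = 0.5 * ac
            dp = max(1, int(rng.poisson(30)))
            ann = "|".join(
                [
                    alt,
                    effect,
                    impact,
                    gene,
                    f"ENSG{gene_idx:011d}",
                    "transcript",
                    f"TX{gene_idx:04d}.1",
                    "protein_coding" if impact != "MODIFIER" else "",
                    f"{int(rng.integers(1, 10))}/10",
                    f"c.{int(rng.integers(1, 2000))}{ref}>{alt}",
                ]
            )
            info: dict[str, str | None] = {
                "AC": str(ac),
                "AF": _fmt(af, 3),
                "AN": "2",
                "ANN": ann,
                "BaseQRankSum": _fmt(float(rng.normal(0, 1)), 3),
                "DP": str(dp),
                "ExcessHet": _fmt(float(rng.uniform(0, 6)), 4),
                "FS": _fmt(float(rng.uniform(0, 10)), 3),
                "MLEAC": str(ac),
                "MLEAF": _fmt(af, 3),
                "MQ": _fmt(float(rng.normal(58, 2)), 2),
                "QD": _fmt(qd, 2),
                "ReadPosRankSum": _fmt(float(rng.normal(0, 1)), 3),
                "SOR": _fmt(float(rng.uniform(0, 3)), 3),
            }
            qual = round(float(rng.uniform(30, 2000)), 2)
            gq = int(rng.integers(30, 100))
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    variant_id=None,
                    ref=str(ref),
                    alt=str(alt),
                    qual=qual,
                    filter_status="PASS",
                    info=info,
                    genotype="0/1" if ac == 1 else "1/1",
                    combined_depth=dp,
                    conditional_genotype_quality=gq,
                )
            )
            cadd_rows.append(
                CaddRow(chrom, pos, str(ref), str(alt), round(raw, 6), round(phred, 2))
            )

        age = round(float(rng.uniform(*spec.age_range)), 1)
        metadata = PatientMetadata(
            accession=accession,
            age=age,
            sex=str(rng.choice(["male", "female"])),
            disease_stage=str(rng.choice(["Mild", "Moderate", "Severe"])),
            tissue="Blood",
        )
        patients.append(PatientData(accession, records, cadd_rows, metadata, impacts))
    return CohortBundle(spec=spec, patients=patients)


_VCF_HEADER = """##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count in genotypes">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Total number of alleles in called genotypes">
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | Feature_Type | Feature_ID | Transcript_BioType | Rank | HGVS.c'">
##INFO=<ID=BaseQRankSum,Number=1,Type=Float,Description="Z-score from Wilcoxon rank sum test of Alt Vs. Ref base qualities">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">
##INFO=<ID=ExcessHet,Number=1,Type=Float,Description="Phred-scaled p-value for exact test of excess heterozygosity">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value using Fisher's exact test to detect strand bias">
##INFO=<ID=MLEAC,Number=A,Type=Integer,Description="Maximum likelihood expectation for the allele counts">
##INFO=<ID=MLEAF,Number=A,Type=Float,Description="Maximum likelihood expectation for the allele frequency">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS Mapping Quality">
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant Confidence/Quality by Depth">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Z-score from Wilcoxon rank sum test of Alt vs. Ref read position bias">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric Odds Ratio of 2x2 contingency table to detect strand bias">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
"""


def _record_to_vcf_line(rec: VariantRecord) -> str:
    info = ";".join(
        k if v is None else f"{k}={v}" for k, v in rec.info.items()
    )
    sample = f"{rec.genotype}:{rec.combined_depth}:{rec.conditional_genotype_quality}"
    return "\t".join(
        [
            rec.chrom,
            str(rec.pos),
            rec.variant_id or ".",
            rec.ref,
            rec.alt,
            format(rec.qual, "g") if rec.qual is not None else ".",
            rec.filter_status,
            info,
            "GT:DP:GQ",
            sample,
        ]
    )


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict[str, list[str]]:
    """Write one VCF + one CADD TSV per patient and one metadata CSV.

    Files re-parse under :mod:`variantkg.vcf_io` into records equal to
    the bundle's.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vcf_paths, cadd_paths = [], []
    for patient in bundle.patients:
        vcf_path = out / f"{patient.accession}.vcf"
        lines = [_VCF_HEADER.rstrip("\n")]
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + patient.accession
        )
        lines.extend(_record_to_vcf_line(r) for r in patient.records)
        vcf_path.write_text("\n".join(lines) + "\n")
        vcf_paths.append(str(vcf_path))

        tsv_path = out / f"{patient.accession}.cadd.tsv"
        tsv_lines = ["#Chrom\tPos\tRef\tAlt\tRawScore\tPHRED"]
        tsv_lines.extend(
            f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.raw_score:.6f}\t{c.phred:.2f}"
            for c in patient.cadd
        )
        tsv_path.write_text("\n".join(tsv_lines) + "\n")
        cadd_paths.append(str(tsv_path))

    meta_path = out / "metadata.csv"
    meta_lines = ["Run,Age,sex,disease_stage,tissue"]
    for patient in bundle.patients:
        m = patient.metadata
        meta_lines.append(
            f"{m.accession},{m.age},{m.sex},{m.disease_stage},{m.tissue}"
        )
    meta_path.write_text("\n".join(meta_lines) + "\n")
    return {"vcf": vcf_paths, "cadd": cadd_paths, "metadata": [str(meta_path)]}
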