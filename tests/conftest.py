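"""Shared fixtures: worked-example inputs and a small synthetic cohort."""

import pathlib

import pytest

from variantkg import graph_build, rdfize, synth
from variantkg.store import QuadStore

# The published conversion example: one SnpCluster-filtered SNV on chr1
# at 16963 (G>A, QUAL 45.64, AF 0.500) with its CADD score row
# (raw 0.900784, PHRED 12.72), run accession SRR13112995.  An ANN token
# is included so the record is visible to the feature-extraction query.
WORKED_ACCESSION = "SRR13112995"
WORKED_DIGEST = "4a37140cdc877d90ffe2b58a8151f27e"
WORKED_ANN = "A|missense_variant|MODERATE|GENE1|ENSG01|transcript|TX1|protein_coding|1/5|c.1T>G"
WORKED_VCF_LINE = (
    "1\t16963\t.\tG\tA\t45.64\tSnpCluster\t"
    "AC=1;AF=0.500;AN=2;BaseQRankSum=1.465;DP=8;ExcessHet=3.0103;FS=0.000;"
    "MLEAC=1;MLEAF=0.500;MQ=60.00;MQRankSum=0.000;QD=5.70;"
    f"ReadPosRankSum=-0.366;SOR=0.169;ANN={WORKED_ANN}\t"
    "GT:AD:DP:GQ:PL\t0/1:6,2:8:53:53,0,228"
)
WORKED_VCF_TEXT = (
    "##fileformat=VCFv4.2\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n"
    + WORKED_VCF_LINE
    + "\n"
)
WORKED_CADD_TEXT = "#Chrom\tPos\tRef\tAlt\tRawScore\tPHRED\n1\t16963\tG\tA\t0.900784\t12.72\n"


@pytest.fixture(scope="session")
def worked_rdf_dir(tmp_path_factory) -> pathlib.Path:
    """Worked-example VCF + CADD TSV converted to RDF."""
    d = tmp_path_factory.mktemp("worked")
    (d / f"{WORKED_ACCESSION}.vcf").write_text(WORKED_VCF_TEXT)
    (d / f"{WORKED_ACCESSION}.cadd.tsv").write_text(WORKED_CADD_TEXT)
    rdfize.rdfize_cohort(
        [d / f"{WORKED_ACCESSION}.vcf"],
        [d / f"{WORKED_ACCESSION}.cadd.tsv"],
        None,
        d / "rdf",
    )
    return d / "rdf"


@pytest.fixture(scope="session")
def small_spec() -> synth.CohortSpec:
    return synth.CohortSpec(n_patients=5, variants_per_patient=40, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_spec) -> synth.CohortBundle:
    return synth.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_cohort_dir(small_bundle, tmp_path_factory) -> pathlib.Path:
    d = tmp_path_factory.mktemp("cohort")
    synth.write_cohort(small_bundle, d)
    return d


@pytest.fixture(scope="session")
def small_rdf_dir(small_cohort_dir, tmp_path_factory) -> pathlib.Path:
    d = tmp_path_factory.mktemp("cohort_rdf")
    rdfize.rdfize_cohort(
        sorted(small_cohort_dir.glob("*.vcf")),
        sorted(small_cohort_dir.glob("*.cadd.tsv")),
        small_cohort_dir / "metadata.csv",
        d,
    )
    return d


@pytest.fixture(scope="session")
def small_store(small_rdf_dir) -> QuadStore:
    store = QuadStore()
    store.load(*sorted(small_rdf_dir.glob("*.nq")), small_rdf_dir / "cadd.ttl")
    return store


@pytest.fixture(scope="session")
def small_table(small_store):
    return small_store.extract_feature_table(small_store.list_accessions())


@pytest.fixture(scope="session")
def small_graph(small_table):
    return graph_build.build_learning_graph(
        small_table, config=graph_build.GraphConfig(seed=1)
    )
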