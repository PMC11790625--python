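"""RDF emission: origin IRIs, variant quads, CADD Turtle, metadata quads."""

import hashlib
import io
import json

import pytest
from rdflib import Dataset, Graph

from variantkg.rdfize import (
    NS,
    XSD,
    Term,
    cadd_to_triples,
    info_key_canonical,
    make_origin_uri,
    metadata_to_quads,
    rdfize_cohort,
    serialize_nquads,
    serialize_turtle,
    variant_to_quads,
)
from variantkg.vcf_io import CaddRow, PatientMetadata, parse_vcf

from .conftest import WORKED_ACCESSION, WORKED_DIGEST, WORKED_VCF_TEXT


def worked_record():
    _, records = parse_vcf(io.StringIO(WORKED_VCF_TEXT))
    return records[0]


class TestOriginUri:
    def test_printed_example(self):
        term = make_origin_uri(WORKED_DIGEST, 0)
        assert term.value == f"origin://{WORKED_DIGEST}@0"

    def test_index_concatenation(self):
        assert make_origin_uri(WORKED_DIGEST, 5).value.endswith("@5")

    @pytest.mark.parametrize("digest", ["XYZ", "ABCDEF" * 6, WORKED_DIGEST.upper()])
    def test_non_hex_rejected(self, digest):
        with pytest.raises(ValueError):
            make_origin_uri(digest, 0)


class TestVariantQuads:
    def test_ref_quad_in_named_graph(self):
        origin = make_origin_uri(WORKED_DIGEST, 0)
        quads = variant_to_quads(worked_record(), origin, WORKED_ACCESSION)
        ref = [q for q in quads if q.predicate.value.endswith("variant/REF")]
        (q,) = ref
        assert q.object.value == NS.vcf2rdf_seq + "G"
        assert q.graph.value == f"sg://{WORKED_ACCESSION}"

    def test_position_is_integer_literal(self):
        quads = variant_to_quads(worked_record(), make_origin_uri(WORKED_DIGEST, 0), WORKED_ACCESSION)
        pos = [q for q in quads if q.predicate.value == NS.faldo + "position"]
        (q,) = pos
        assert q.object.value == "16963"
        assert q.object.datatype == XSD.integer

    def test_exactly_one_position_quad_per_record(self, small_bundle):
        for patient in small_bundle.patients[:2]:
            for i, rec in enumerate(patient.records):
                quads = variant_to_quads(rec, make_origin_uri("0" * 32, i), patient.accession)
                pos = [q for q in quads if q.predicate.value == NS.faldo + "position"]
                assert len(pos) == 1
                assert pos[0].object.value == str(rec.pos)

    def test_minimal_record_emits_six_core_quads(self):
        from variantkg.vcf_io import VariantRecord

        rec = VariantRecord(chrom="1", pos=5, ref="A", alt="T", qual=1.0)
        quads = variant_to_quads(rec, make_origin_uri("0" * 32, 0), "ACC")
        assert len(quads) == 6
        locals_ = {q.predicate.value.rsplit("/", 1)[-1].rsplit("#", 1)[-1] for q in quads}
        assert locals_ == {"reference", "position", "REF", "ALT", "QUAL", "FILTER_STATUS"}


class TestInfoKeyCanonical:
    @pytest.mark.parametrize(
        "key, expected",
        [
            ("AF", "ALLELE_FREQUENCY"),
            ("MQ", "RMS_MAPPING_QUALITY"),
            ("AC", "ALLELE_COUNT"),
            ("AN", "TOTAL_NUMBER_OF_ALLELES"),
            ("DP", "DEPTH"),
            ("ANN", "ANN"),
            ("FOO", "FOO"),
            ("MQRankSum", "MQRANKSUM"),
        ],
    )
    def test_mapping(self, key, expected):
        assert info_key_canonical(key) == expected


class TestCaddTriples:
    def test_worked_row_node_and_properties(self):
        row = CaddRow("1", 16963, "G", "A", 0.900784, 12.72)
        quads = cadd_to_triples(row, WORKED_ACCESSION, 1)
        node = quads[0].subject.value
        assert node == f"http://sg.org/{WORKED_ACCESSION}/1/variant1"
        by_pred = {q.predicate.value.rsplit("/", 1)[-1]: q.object.value for q in quads}
        assert by_pred["has_pos"] == "16963"
        assert by_pred["has_ref_genome"] == "G"
        assert by_pred["has_alt_genome"] == "A"

    def test_cadd_child_node_scores(self):
        quads = cadd_to_triples(CaddRow("1", 16963, "G", "A", 0.900784, 12.72), WORKED_ACCESSION, 1)
        cadd_node = f"http://sg.org/{WORKED_ACCESSION}/1/variant1/cadd"
        scores = {
            q.predicate.value.rsplit("/", 1)[-1]: q.object.value
            for q in quads
            if q.subject.value == cadd_node
        }
        assert float(scores["has_raw_score"]) == pytest.approx(0.900784)
        assert float(scores["has_phred"]) == pytest.approx(12.72)

    def test_per_chromosome_counter(self):
        q1 = cadd_to_triples(CaddRow("2", 10, "G", "A", 0.1, 1.0), "ACC", 1)
        q2 = cadd_to_triples(CaddRow("2", 20, "G", "A", 0.2, 2.0), "ACC", 2)
        assert q1[0].subject.value.endswith("/2/variant1")
        assert q2[0].subject.value.endswith("/2/variant2")

    def test_triples_live_in_default_graph(self):
        quads = cadd_to_triples(CaddRow("1", 1, "G", "A", 0.1, 1.0), "ACC", 1)
        assert all(q.graph is None for q in quads)


class TestMetadataQuads:
    def test_age_quad_matches_ontology(self):
        patient = PatientMetadata(accession="SRR12570589", age=61.0)
        quads = metadata_to_quads(patient)
        (q,) = [q for q in quads if "Q11904283" in q.predicate.value]
        assert q.subject.value == NS.sra + "SRR12570589"
        assert q.object.value == "61.0"
        assert q.object.datatype == XSD.float
        assert q.graph.value == "sg://SRR12570589"

    def test_accession_only_patient_yields_nothing(self):
        assert metadata_to_quads(PatientMetadata(accession="SRR1")) == []

    def test_unmapped_field_skipped_with_warning(self):
        patient = PatientMetadata(accession="SRR1", age=30.0, sex="male")
        with pytest.warns(UserWarning, match="sex"):
            quads = metadata_to_quads(patient, {"age": NS.wikidata + "Q11904283"})
        assert len(quads) == 1


class TestSerialization:
    def test_nquads_roundtrip_through_standard_grammar(self, tmp_path):
        origin = make_origin_uri(WORKED_DIGEST, 0)
        quads = variant_to_quads(worked_record(), origin, WORKED_ACCESSION)
        text = serialize_nquads(quads)
        p = tmp_path / "x.nq"
        p.write_text(text)
        ds = Dataset(default_union=False)
        ds.parse(str(p), format="nquads")
        assert len(list(ds.quads((None, None, None, None)))) == len(quads)
        graphs = {str(g.identifier) for g in ds.contexts() if len(g)}
        assert graphs == {f"sg://{WORKED_ACCESSION}"}

    def test_turtle_parses_and_has_no_graph_component(self, tmp_path):
        quads = cadd_to_triples(CaddRow("1", 16963, "G", "A", 0.900784, 12.72), WORKED_ACCESSION, 1)
        text = serialize_turtle(quads)
        g = Graph()
        g.parse(data=text, format="turtle")
        assert len(g) == len(quads)


class TestRdfizeCohort:
    def test_outputs_and_manifest(self, small_cohort_dir, tmp_path):
        manifest = rdfize_cohort(
            sorted(small_cohort_dir.glob("*.vcf")),
            sorted(small_cohort_dir.glob("*.cadd.tsv")),
            small_cohort_dir / "metadata.csv",
            tmp_path,
        )
        assert len(manifest["accessions"]) == 5
        assert len(list(tmp_path.glob("*.nq"))) == 5
        assert (tmp_path / "cadd.ttl").exists()
        assert json.loads((tmp_path / "manifest.json").read_text()) == manifest

    def test_order_and_workers_invariance(self, small_cohort_dir, tmp_path):
        vcfs = sorted(small_cohort_dir.glob("*.vcf"))
        tsvs = sorted(small_cohort_dir.glob("*.cadd.tsv"))

        def digest_dir(d):
            return {
                p.name: hashlib.md5(p.read_bytes()).hexdigest()
                for p in sorted(d.iterdir())
            }

        rdfize_cohort(vcfs, tsvs, None, tmp_path / "a")
        rdfize_cohort(list(reversed(vcfs)), list(reversed(tsvs)), None, tmp_path / "b")
        rdfize_cohort(vcfs, tsvs, None, tmp_path / "c", workers=4)
        assert digest_dir(tmp_path / "a") == digest_dir(tmp_path / "b") == digest_dir(tmp_path / "c")

    def test_accession_collision_rejected(self, small_cohort_dir, tmp_path):
        vcf = sorted(small_cohort_dir.glob("*.vcf"))[0]
        dup = tmp_path / "copy" / vcf.name
        dup.parent.mkdir()
        dup.write_text(vcf.read_text())
        with pytest.raises(ValueError, match="collision"):
            rdfize_cohort([vcf, dup], [], None, tmp_path / "out")
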