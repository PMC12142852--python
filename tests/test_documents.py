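"""Sample XML, receipts, manifests and staging."""

import pytest
from hypothesis import given, settings, strategies as st
from lxml import etree

from mgbroker.documents import (
    Manifest,
    build_manifest,
    build_receipt,
    build_sample_set,
    build_virtual_sample,
    format_coverage,
    parse_receipt,
    stage_item,
    wrap_sample_set,
)
from mgbroker.errors import (
    DocumentError,
    ReceiptParseError,
    StagingError,
    UnresolvedReferenceError,
)
from mgbroker.model import (
    AccessionLedger,
    AssemblyRecord,
    Assignment,
    BinRecord,
    Level,
    MagRecord,
    ObjectKind,
    QualityStats,
    ReadSetRecord,
    SampleRecord,
    TaxonomyAssignment,
)


def sample(alias="s1", **attrs):
    return SampleRecord(alias=alias, title=f"sample {alias}",
                        scientific_name="sediment metagenome", taxid=749907,
                        collection_date="2023-06-14", location="Germany",
                        attributes=attrs)


def a_bin(bin_id="bin_7"):
    return BinRecord(bin_id=bin_id, fasta_path=f"{bin_id}.fa",
                     binning_software="MetaBAT 2",
                     quality=QualityStats(95.0, 2.0))


ASSIGNMENT = TaxonomyAssignment("uncultured bacterium", 77133)


class TestSampleSet:
    def test_cardinality(self):
        doc = etree.fromstring(build_sample_set([sample("s1"), sample("s2")]).encode())
        assert len(doc.findall("SAMPLE")) == 2

    def test_attributes_survive_roundtrip(self):
        xml = build_sample_set([sample("s1", ph="7.2", depth="12 m")])
        doc = etree.fromstring(xml.encode())
        pairs = {el.findtext("TAG"): el.findtext("VALUE")
                 for el in doc.iter("SAMPLE_ATTRIBUTE")}
        assert pairs["ph"] == "7.2" and pairs["depth"] == "12 m"
        assert doc.find("SAMPLE/SAMPLE_NAME/TAXON_ID").text == "749907"

    def test_duplicate_aliases_rejected_before_serialization(self):
        with pytest.raises(DocumentError, match="s1"):
            build_sample_set([sample("s1"), sample("s1")])

    def test_empty_set_rejected(self):
        with pytest.raises(DocumentError):
            build_sample_set([])


class TestVirtualSample:
    def test_derived_from_single_origin(self):
        ledger = AccessionLedger().add("s1", ObjectKind.SAMPLE, "ERS0000001")
        el = build_virtual_sample(a_bin(), ASSIGNMENT, ledger, origin_refs=["s1"])
        pairs = {e.findtext("TAG"): e.findtext("VALUE")
                 for e in el.iter("SAMPLE_ATTRIBUTE")}
        assert pairs["sample derived from"] == "ERS0000001"
        assert pairs["completeness score"] == "95.0"
        assert pairs["binning software"] == "MetaBAT 2"

    def test_coassembly_lists_all_origins(self):
        ledger = (AccessionLedger()
                  .add("s1", ObjectKind.SAMPLE, "ERS0000001")
                  .add("s2", ObjectKind.SAMPLE, "ERS0000002"))
        asm = AssemblyRecord(name="co", program="spades", sample_refs=["s1", "s2"],
                             run_refs=[], fasta_path="co.fa",
                             molecule_type="genomic DNA")
        el = build_virtual_sample(asm, ASSIGNMENT, ledger)
        pairs = {e.findtext("TAG"): e.findtext("VALUE")
                 for e in el.iter("SAMPLE_ATTRIBUTE")}
        assert pairs["sample derived from"] == "ERS0000001,ERS0000002"

    def test_missing_origin_alias_fails(self):
        with pytest.raises(UnresolvedReferenceError):
            build_virtual_sample(a_bin(), ASSIGNMENT, AccessionLedger(),
                                 origin_refs=["ghost"])

    def test_environmental_taxon_on_element(self):
        ledger = AccessionLedger().add("s1", ObjectKind.SAMPLE, "ERS0000001")
        el = build_virtual_sample(a_bin(), ASSIGNMENT, ledger, origin_refs=["s1"])
        assert el.findtext("SAMPLE_NAME/TAXON_ID") == "77133"
        assert el.findtext("SAMPLE_NAME/SCIENTIFIC_NAME") == "uncultured bacterium"


class TestReceipt:
    def test_success_with_assignments(self):
        xml = build_receipt(True, [
            Assignment(ObjectKind.SAMPLE, "s1", "ERS0000001"),
            Assignment(ObjectKind.SAMPLE, "s2", "ERS0000002")])
        receipt = parse_receipt(xml)
        assert receipt.success and len(receipt.assignments) == 2
        assert receipt.assignments[0] == Assignment(ObjectKind.SAMPLE, "s1",
                                                    "ERS0000001")
        assert not receipt.errors

    def test_failure_with_error_message(self):
        receipt = parse_receipt(build_receipt(False, messages=[
            ("ERROR", "object(s) already exist: s1")]))
        assert not receipt.success and receipt.assignments == []
        assert receipt.errors == ["object(s) already exist: s1"]

    def test_info_only_success_allows_empty_assignments(self):
        receipt = parse_receipt(build_receipt(True, messages=[
            ("INFO", "validation only")]))
        assert receipt.success and receipt.assignments == []

    def test_malformed_xml(self):
        with pytest.raises(ReceiptParseError):
            parse_receipt("<RECEIPT success='true'")

    def test_missing_success_attribute(self):
        with pytest.raises(ReceiptParseError, match="success"):
            parse_receipt("<RECEIPT><SAMPLE alias='a' accession='ERS1'/></RECEIPT>")


def _ledger():
    return (AccessionLedger()
            .add("s1", ObjectKind.SAMPLE, "ERS0000001")
            .add("vs1", ObjectKind.SAMPLE, "ERS0000002")
            .add("r1", ObjectKind.RUN, "ERR0000001"))


class TestManifest:
    def test_paired_reads_manifest(self):
        rs = ReadSetRecord(alias="r1", sample_ref="s1", platform="ILLUMINA",
                           instrument="HiSeq", library_layout="PAIRED",
                           library_source="METAGENOMIC",
                           library_selection="RANDOM", library_strategy="WGS",
                           files=["a_1.fastq", "a_2.fastq"])
        m = build_manifest(Level.READS, rs, _ledger(), "PRJEB00001")
        assert m.get_all("FASTQ") == ["a_1.fastq", "a_2.fastq"]
        assert m.get("SAMPLE") == "ERS0000001"
        assert m.get("LIBRARY_STRATEGY") == "WGS"

    def test_bin_coverage_one_decimal(self):
        m = build_manifest(Level.BINS, a_bin(), _ledger(), "PRJEB00001",
                           sample_ref="vs1", coverage=12.34, platform="ILLUMINA",
                           program="spades")
        assert m.get("COVERAGE") == "12.3"
        assert m.get("ASSEMBLY_TYPE") == "binned metagenome"

    def test_mag_assembly_type(self):
        mag = MagRecord(bin_id="mag_1", fasta_path="mag_1.fa",
                        binning_software="MetaBAT 2")
        m = build_manifest(Level.MAGS, mag, _ledger(), "PRJEB00001",
                           sample_ref="vs1", coverage=5.0, platform="ILLUMINA",
                           program="spades")
        assert m.get("ASSEMBLY_TYPE") == "Metagenome-Assembled Genome (MAG)"

    def test_primary_metagenome_type_with_run_refs(self):
        asm = AssemblyRecord(name="co", program="spades", sample_refs=["s1"],
                             run_refs=["r1"], fasta_path="co.fa",
                             molecule_type="genomic DNA", coverage=3.25)
        m = build_manifest(Level.ASSEMBLY, asm, _ledger(), "PRJEB00001",
                           sample_ref="s1", run_refs=["r1"], platform="ILLUMINA")
        assert m.get("ASSEMBLY_TYPE") == "primary metagenome"
        assert m.get("RUN_REF") == "ERR0000001"

    def test_missing_dependency_names_key(self):
        with pytest.raises(UnresolvedReferenceError, match="SAMPLE"):
            build_manifest(Level.BINS, a_bin(), AccessionLedger(), "PRJEB00001",
                           sample_ref="ghost", coverage=1.0)

    def test_round_half_even_formatting(self):
        assert format_coverage(12.25) == "12.2"
        assert format_coverage(12.35) == "12.3"

    @given(st.lists(st.tuples(
        st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ_", min_size=1, max_size=12),
        st.text(alphabet=st.characters(blacklist_characters="\t\n\r",
                                       blacklist_categories=("Cs",)),
                max_size=30)), max_size=15))
    @settings(max_examples=60, deadline=None)
    def test_serialize_parse_roundtrip(self, entries):
        m = Manifest()
        for k, v in entries:
            m.add(k, v)
        assert Manifest.parse(m.serialize()).entries == m.entries

    def test_tab_in_value_rejected(self):
        with pytest.raises(DocumentError):
            Manifest().add("KEY", "a\tb")


class TestStaging:
    def _manifest(self, fasta):
        return (Manifest().add("STUDY", "PRJEB00001").add("SAMPLE", "ERS0000001")
                .add("FASTA", str(fasta)))

    def test_bin_staging_layout(self, tmp_path):
        fasta = tmp_path / "bin_7.fa"
        fasta.write_text(">c1\nACGT\n")
        staged = stage_item(a_bin(), self._manifest(fasta), tmp_path / "work",
                            Level.BINS, "bin_7")
        assert staged.staging_dir == tmp_path / "work" / "bins" / "bin_7"
        assert sorted(p.name for p in staged.staging_dir.iterdir()) == \
            ["bin_7.fa", "manifest.tsv"]
        # manifest now references the staged copy, not the original path
        assert Manifest.parse(staged.manifest_path.read_text()).get("FASTA") == \
            "bin_7.fa"

    def test_restaging_is_byte_identical(self, tmp_path):
        fasta = tmp_path / "bin_7.fa"
        fasta.write_text(">c1\nACGT\n")
        first = stage_item(a_bin(), self._manifest(fasta), tmp_path / "work",
                           Level.BINS, "bin_7")
        content = first.manifest_path.read_bytes()
        second = stage_item(a_bin(), self._manifest(fasta), tmp_path / "work",
                            Level.BINS, "bin_7")
        assert second.manifest_path.read_bytes() == content

    def test_foreign_directory_collision(self, tmp_path):
        target = tmp_path / "work" / "bins" / "bin_7"
        target.mkdir(parents=True)
        (target / "precious.txt").write_text("do not touch")
        fasta = tmp_path / "bin_7.fa"
        fasta.write_text(">c1\nACGT\n")
        with pytest.raises(StagingError):
            stage_item(a_bin(), self._manifest(fasta), tmp_path / "work",
                       Level.BINS, "bin_7")

    def test_missing_data_file(self, tmp_path):
        with pytest.raises(StagingError):
            stage_item(a_bin(), self._manifest(tmp_path / "ghost.fa"),
                       tmp_path / "work", Level.BINS, "bin_7")


def test_wrap_sample_set_counts():
    ledger = AccessionLedger().add("s1", ObjectKind.SAMPLE, "ERS0000001")
    el = build_virtual_sample(a_bin(), ASSIGNMENT, ledger, origin_refs=["s1"])
    doc = etree.fromstring(wrap_sample_set([el]).encode())
    assert len(doc.findall("SAMPLE")) == 1
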