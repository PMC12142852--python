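"""Registry-facing documents: sample-set XML, receipts, manifests, staging.

Sample metadata travels as XML sample sets; file-bearing objects (reads,
assemblies, bins, MAGs) travel as a tab-separated KEY/VALUE manifest staged
alongside the data file, in the style of the Webin submission broker.  The
registry answers every submission with a receipt carrying a success flag,
messages, and the assigned accessions.

Documents are serialized with a fixed element/attribute order so that
repeated runs produce byte-identical output.
"""

from __future__ import annotations

import hashlib
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from lxml import etree

from .errors import (
    DocumentError,
    ReceiptParseError,
    StagingError,
    UnresolvedReferenceError,
)
from .model import (
    AccessionLedger,
    AssemblyRecord,
    Assignment,
    BinRecord,
    Level,
    MagRecord,
    ObjectKind,
    Receipt,
    ReadSetRecord,
    SampleRecord,
    TaxonomyAssignment,
)
from .readers import CoverageStats

# Default checklist identifier attached to virtual samples of binned genomes;
# checklists evolve, so this is a parameter, not a constant of the format.
DEFAULT_BINNED_CHECKLIST = "ERC000050"

# Mandatory manifest keys per level, Webin-style.  FASTQ appears once or
# twice according to the library layout; RUN_REF is optional everywhere.
MANDATORY_MANIFEST_KEYS: dict[Level, tuple[str, ...]] = {
    Level.READS: ("STUDY", "SAMPLE", "NAME", "PLATFORM", "INSTRUMENT",
                  "LIBRARY_SOURCE", "LIBRARY_SELECTION", "LIBRARY_STRATEGY",
                  "FASTQ"),
    Level.ASSEMBLY: ("STUDY", "SAMPLE", "ASSEMBLYNAME", "ASSEMBLY_TYPE",
                     "COVERAGE", "PROGRAM", "PLATFORM", "MOLECULETYPE", "FASTA"),
    Level.BINS: ("STUDY", "SAMPLE", "ASSEMBLYNAME", "ASSEMBLY_TYPE",
                 "COVERAGE", "PROGRAM", "PLATFORM", "MOLECULETYPE", "FASTA"),
    Level.MAGS: ("STUDY", "SAMPLE", "ASSEMBLYNAME", "ASSEMBLY_TYPE",
                 "COVERAGE", "PROGRAM", "PLATFORM", "MOLECULETYPE", "FASTA"),
}

ASSEMBLY_TYPE_BY_LEVEL = {
    Level.ASSEMBLY: "primary metagenome",
    Level.BINS: "binned metagenome",
    Level.MAGS: "Metagenome-Assembled Genome (MAG)",
}

_FILE_KEYS = {"FASTA", "FASTQ"}


@dataclass
class Manifest:
    """Ordered KEY/VALUE metadata block staged next to an uploaded file."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, key: str, value: str) -> "Manifest":
        key = key.upper()
        if any(c in str(value) for c in "\t\n\r"):
            raise DocumentError(
                f"manifest value for {key} contains a tab or line break")
        self.entries.append((key, str(value)))
        return self

    def get(self, key: str) -> str | None:
        for k, v in self.entries:
            if k == key:
                return v
        return None

    def get_all(self, key: str) -> list[str]:
        return [v for k, v in self.entries if k == key]

    def keys(self) -> list[str]:
        return [k for k, _ in self.entries]

    def serialize(self) -> str:
        return "".join(f"{k}\t{v}\n" for k, v in self.entries)

    @classmethod
    def parse(cls, text: str) -> "Manifest":
        m = cls()
        for line in text.split("\n"):
            if not line:
                continue
            key, _, value = line.partition("\t")
            m.add(key, value)
        return m


def _sample_element(alias: str, taxid: int, scientific_name: str, title: str,
                    attributes: Sequence[tuple[str, str]]) -> etree._Element:
    sample = etree.Element("SAMPLE", alias=alias)
    etree.SubElement(sample, "TITLE").text = title
    name_el = etree.SubElement(sample, "SAMPLE_NAME")
    etree.SubElement(name_el, "TAXON_ID").text = str(taxid)
    etree.SubElement(name_el, "SCIENTIFIC_NAME").text = scientific_name
    if attributes:
        attrs_el = etree.SubElement(sample, "SAMPLE_ATTRIBUTES")
        for tag, value in attributes:
            attr = etree.SubElement(attrs_el, "SAMPLE_ATTRIBUTE")
            etree.SubElement(attr, "TAG").text = tag
            etree.SubElement(attr, "VALUE").text = str(value)
    return sample


def serialize_document(root: etree._Element) -> str:
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()


def build_sample_set(samples: Sequence[SampleRecord]) -> str:
    """Serialize study samples as a SAMPLE_SET document."""
    if not samples:
        raise DocumentError("cannot build a sample set from zero samples")
    aliases = [s.alias for s in samples]
    if len(set(aliases)) != len(aliases):
        dupes = sorted({a for a in aliases if aliases.count(a) > 1})
        raise DocumentError(f"duplicate sample aliases: {dupes}")
    root = etree.Element("SAMPLE_SET")
    for s in samples:
        attrs = [("collection date", s.collection_date),
                 ("geographic location (country and/or sea)", s.location)]
        attrs += list(s.attributes.items())
        root.append(_sample_element(s.alias, s.taxid, s.scientific_name,
                                    s.title, attrs))
    return serialize_document(root)


def virtual_sample_alias(item: BinRecord | MagRecord | AssemblyRecord) -> str:
    name = item.bin_id if isinstance(item, BinRecord) else item.name
    return f"{name}_virtual_sample"


def build_virtual_sample(
    item: BinRecord | MagRecord | AssemblyRecord,
    assignment: TaxonomyAssignment,
    ledger: AccessionLedger,
    origin_refs: Sequence[str] | None = None,
    checklist: str = DEFAULT_BINNED_CHECKLIST,
) -> etree._Element:
    """Sample element for a derived object (bin/MAG/co-assembly).

    The element carries the environmental taxon and a "sample derived from"
    attribute listing the resolved accessions of the origin samples
    (comma-separated for co-assemblies).  Origin refs default to the item's
    own sample refs (assemblies); bins/MAGs inherit their assembly's.
    """
    if origin_refs is None:
        if isinstance(item, AssemblyRecord):
            origin_refs = item.sample_refs
        else:
            raise UnresolvedReferenceError(
                f"no origin sample refs available for {virtual_sample_alias(item)}")
    derived_from = ",".join(ledger.resolve(ref) for ref in origin_refs)
    attrs: list[tuple[str, str]] = [("ENA-CHECKLIST", checklist)]
    if isinstance(item, BinRecord):
        if item.quality is not None:
            attrs.append(("completeness score", f"{item.quality.completeness}"))
            attrs.append(("contamination score", f"{item.quality.contamination}"))
        attrs.append(("binning software", item.binning_software))
    attrs.append(("sample derived from", derived_from))
    alias = virtual_sample_alias(item)
    title = f"virtual sample for {item.bin_id if isinstance(item, BinRecord) else item.name}"
    return _sample_element(alias, assignment.taxid, assignment.scientific_name,
                           title, attrs)


def wrap_sample_set(elements: Sequence[etree._Element]) -> str:
    root = etree.Element("SAMPLE_SET")
    for el in elements:
        root.append(el)
    return serialize_document(root)


_RECEIPT_KINDS = {"SAMPLE": ObjectKind.SAMPLE, "RUN": ObjectKind.RUN,
                  "ANALYSIS": ObjectKind.ANALYSIS, "STUDY": ObjectKind.STUDY}


def parse_receipt(text: str) -> Receipt:
    """Parse a registry receipt into success state, assignments and messages."""
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as exc:
        raise ReceiptParseError(f"receipt is not well-formed XML: {exc}") from exc
    if root.tag != "RECEIPT":
        raise ReceiptParseError(f"expected RECEIPT root, found {root.tag!r}")
    success_attr = root.get("success")
    if success_attr is None:
        raise ReceiptParseError("receipt lacks the success attribute")
    success = success_attr.strip().lower() == "true"
    assignments = []
    messages: list[tuple[str, str]] = []
    for child in root:
        if child.tag in _RECEIPT_KINDS and child.get("accession"):
            assignments.append(Assignment(_RECEIPT_KINDS[child.tag],
                                          child.get("alias", ""),
                                          child.get("accession")))
        elif child.tag == "MESSAGES":
            for msg in child:
                messages.append((msg.tag.upper(), msg.text or ""))
    return Receipt(success, assignments, messages)


def build_receipt(success: bool, assignments: Sequence[Assignment] = (),
                  messages: Sequence[tuple[str, str]] = ()) -> str:
    """Serialize a receipt document (used by the mock registry)."""
    root = etree.Element("RECEIPT", success="true" if success else "false")
    for a in assignments:
        etree.SubElement(root, a.kind.value, alias=a.alias, accession=a.accession)
    if messages:
        msgs = etree.SubElement(root, "MESSAGES")
        for severity, text in messages:
            etree.SubElement(msgs, severity.upper()).text = text
    return serialize_document(root)


def format_coverage(value: float) -> str:
    return f"{float(value):.1f}"


def build_manifest(
    level: Level,
    record: ReadSetRecord | AssemblyRecord | BinRecord | MagRecord,
    ledger: AccessionLedger,
    study_ref: str,
    sample_ref: str | None = None,
    assignment: TaxonomyAssignment | None = None,
    coverage: CoverageStats | float | None = None,
    run_refs: Sequence[str] = (),
    platform: str | None = None,
    program: str | None = None,
    molecule_type: str | None = None,
) -> Manifest:
    """Webin-style manifest for one uploadable item.

    All dependencies (study, sample, runs) are resolved through the ledger, so
    a missing upstream accession surfaces as an unresolved-reference error
    naming the offending key.
    """
    def resolve(ref: str, key: str) -> str:
        try:
            return ledger.resolve(ref)
        except UnresolvedReferenceError as exc:
            raise UnresolvedReferenceError(f"{key}: {exc}") from exc

    m = Manifest()
    m.add("STUDY", resolve(study_ref, "STUDY"))
    if level is Level.READS:
        assert isinstance(record, ReadSetRecord)
        m.add("SAMPLE", resolve(record.sample_ref, "SAMPLE"))
        m.add("NAME", record.alias)
        m.add("PLATFORM", record.platform)
        m.add("INSTRUMENT", record.instrument)
        m.add("LIBRARY_SOURCE", record.library_source)
        m.add("LIBRARY_SELECTION", record.library_selection)
        m.add("LIBRARY_STRATEGY", record.library_strategy)
        for f in record.files:
            m.add("FASTQ", f)
        return m

    if sample_ref is None:
        raise UnresolvedReferenceError("SAMPLE: no sample reference supplied")
    m.add("SAMPLE", resolve(sample_ref, "SAMPLE"))
    name = record.bin_id if isinstance(record, BinRecord) else record.name
    m.add("ASSEMBLYNAME", name)
    m.add("ASSEMBLY_TYPE", ASSEMBLY_TYPE_BY_LEVEL[level])
    cov = coverage.fold if isinstance(coverage, CoverageStats) else coverage
    if cov is None:
        cov = getattr(record, "coverage", None)
    if cov is None:
        raise UnresolvedReferenceError("COVERAGE: no coverage value available")
    m.add("COVERAGE", format_coverage(cov))
    m.add("PROGRAM", program or getattr(record, "program", None)
          or getattr(record, "binning_software", ""))
    m.add("PLATFORM", platform or getattr(record, "platform", None) or "")
    m.add("MOLECULETYPE", molecule_type or getattr(record, "molecule_type", None)
          or "genomic DNA")
    m.add("FASTA", record.fasta_path)
    for ref in run_refs:
        m.add("RUN_REF", resolve(ref, "RUN_REF"))
    return m


@dataclass
class StagedItem:
    staging_dir: Path
    manifest_path: Path
    data_paths: list[Path]
    level: Level


def stage_item(record, manifest: Manifest, workdir: str | Path,
               level: Level, alias: str, link: bool = False) -> StagedItem:
    """Assemble the per-item upload bundle: manifest plus data files.

    Layout is ``<workdir>/<level>/<alias>/``; file-bearing manifest keys are
    rewritten to the staged locations.  Re-staging the same item overwrites
    cleanly and deterministically; a collision with a directory this package
    did not create is an error.
    """
    staging_dir = Path(workdir) / level.value.lower() / alias
    marker = staging_dir / "manifest.tsv"
    if staging_dir.exists():
        if any(staging_dir.iterdir()) and not marker.exists():
            raise StagingError(
                f"{staging_dir} exists, is not empty, and is not a staging directory")
        shutil.rmtree(staging_dir)
    try:
        staging_dir.mkdir(parents=True)
    except OSError as exc:
        raise StagingError(f"cannot create staging directory {staging_dir}: {exc}")

    staged = Manifest()
    data_paths = []
    for key, value in manifest.entries:
        if key in _FILE_KEYS:
            src = Path(value)
            if not src.is_file():
                raise StagingError(f"data file missing: {src}")
            dest = staging_dir / src.name
            if link:
                dest.symlink_to(src.resolve())
            else:
                shutil.copyfile(src, dest)
            data_paths.append(dest)
            staged.add(key, dest.name)
        else:
            staged.add(key, value)
    marker.write_text(staged.serialize(), encoding="utf-8", newline="")
    return StagedItem(staging_dir, marker, data_paths, level)


def md5_of(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
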