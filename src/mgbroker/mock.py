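"""Deterministic offline stand-ins for the registry, uploader and datasets.

The real submission targets a remote registry (sample XML + receipts), a
taxonomy query endpoint, and a manifest-driven upload broker.  This module
provides in-process doubles for all three with fully deterministic behaviour
— accessions are issued sequentially per object kind with the same shapes the
public registry uses — plus a local HTTP stub exposing the same contracts for
transport-level testing, and a toy-dataset generator producing a complete,
internally consistent miniature study (reads, co-assembly, bins, quality and
classification tables, alignment map, filled configuration).
"""

from __future__ import annotations

import json
import random
import shutil
import threading
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path

import yaml
from lxml import etree

from .documents import (
    MANDATORY_MANIFEST_KEYS,
    Manifest,
    build_receipt,
)
from .errors import DatasetError, TransportError
from .model import Assignment, Level, ObjectKind, Receipt, TaxonRecord
from .taxonomy import FixtureTaxonomyClient, default_fixture_path

_ACCESSION_PREFIX = {ObjectKind.SAMPLE: "ERS", ObjectKind.RUN: "ERR",
                     ObjectKind.ANALYSIS: "ERZ"}


class MockRegistry:
    """Registry double: sequential accessions, duplicate-alias rejection.

    Accessions are issued per object kind as ``<prefix><7-digit counter>``
    (ERS0000001, ERR0000001, ERZ0000001, ...).  An alias is never issued two
    accessions; resubmitting one yields a failure receipt, like the live
    service.  Failures are always receipts, never exceptions — this emulates
    a server.
    """

    def __init__(self, taxonomy_fixture: str | Path | None = None,
                 auth_token: str | None = None):
        self.counters = {k: 0 for k in _ACCESSION_PREFIX}
        self.issued: dict[str, str] = {}
        self.taxonomy = FixtureTaxonomyClient(taxonomy_fixture)
        self.auth_token = auth_token
        self.register_calls = 0
        self.query_calls = 0

    def next_accession(self, kind: ObjectKind) -> str:
        self.counters[kind] += 1
        return f"{_ACCESSION_PREFIX[kind]}{self.counters[kind]:07d}"

    def register(self, xml_text: str) -> str:
        self.register_calls += 1
        try:
            root = etree.fromstring(xml_text.encode())
        except etree.XMLSyntaxError as exc:
            return build_receipt(False, messages=[("ERROR", f"cannot parse payload: {exc}")])
        aliases = [el.get("alias") for el in root.iter("SAMPLE") if el.get("alias")]
        if not aliases:
            return build_receipt(False, messages=[("ERROR", "no aliased objects in payload")])
        dupes = [a for a in aliases if a in self.issued]
        if dupes:
            return build_receipt(False, messages=[
                ("ERROR", f"object(s) already exist: {', '.join(dupes)}")])
        assignments = []
        for alias in aliases:
            accession = self.next_accession(ObjectKind.SAMPLE)
            self.issued[alias] = accession
            assignments.append(Assignment(ObjectKind.SAMPLE, alias, accession))
        return build_receipt(True, assignments)

    def taxonomy_query(self, name: str) -> list[TaxonRecord]:
        self.query_calls += 1
        return self.taxonomy.query(name)


class MockUploader:
    """Upload-broker double: validates the staged manifest, issues accessions.

    Checks the mandatory key table for the item's level and the presence of
    every staged data file; missing pieces produce a failure receipt naming
    the offending key.  Reads receive RUN accessions, everything else
    ANALYSIS accessions, drawn from the shared registry counters.
    """

    def __init__(self, registry: MockRegistry):
        self.registry = registry
        self.upload_calls = 0

    def __call__(self, staged) -> Receipt:
        self.upload_calls += 1
        if not staged.manifest_path.is_file():
            return Receipt(False, [], [("ERROR", "staging directory has no manifest")])
        manifest = Manifest.parse(staged.manifest_path.read_text())
        for key in MANDATORY_MANIFEST_KEYS[staged.level]:
            if manifest.get(key) is None:
                return Receipt(False, [], [("ERROR", f"missing mandatory key {key}")])
        for key in ("FASTA", "FASTQ"):
            for name in manifest.get_all(key):
                if not (staged.staging_dir / name).is_file():
                    return Receipt(False, [], [("ERROR", f"{key} file {name} not staged")])
        alias = manifest.get("NAME") or manifest.get("ASSEMBLYNAME")
        if alias in self.registry.issued:
            return Receipt(False, [], [("ERROR", f"object(s) already exist: {alias}")])
        kind = ObjectKind.RUN if staged.level is Level.READS else ObjectKind.ANALYSIS
        accession = self.registry.next_accession(kind)
        self.registry.issued[alias] = accession
        return Receipt(True, [Assignment(kind, alias, accession)], [])


# ---------------------------------------------------------------------------
# local HTTP stub + clients (transport-level contract)


class _Handler(BaseHTTPRequestHandler):
    registry: MockRegistry = None  # set on the server class

    def _authorized(self) -> bool:
        token = self.server.registry.auth_token
        return token is None or self.headers.get("Authorization") == f"Bearer {token}"

    def do_POST(self):
        if not self._authorized():
            self.send_error(401)
            return
        length = int(self.headers.get("Content-Length", 0))
        body = self.rfile.read(length).decode()
        if self.path == "/submit":
            receipt = self.server.registry.register(body)
        elif self.path == "/upload":
            # the upload broker runs next to the staged files, so the stub
            # receives the staging location rather than the bytes themselves
            from .documents import StagedItem
            spec = json.loads(body)
            staged = StagedItem(Path(spec["staging_dir"]),
                                Path(spec["staging_dir"]) / "manifest.tsv",
                                [], Level(spec["level"]))
            result = self.server.uploader(staged)
            receipt = build_receipt(result.success, result.assignments,
                                    result.messages)
        else:
            self.send_error(404)
            return
        payload = receipt.encode()
        self.send_response(200)
        self.send_header("Content-Type", "application/xml")
        self.send_header("Content-Length", str(len(payload)))
        self.end_headers()
        self.wfile.write(payload)

    def do_GET(self):
        if not self._authorized():
            self.send_error(401)
            return
        parsed = urllib.parse.urlparse(self.path)
        if parsed.path != "/taxonomy":
            self.send_error(404)
            return
        name = urllib.parse.parse_qs(parsed.query).get("name", [""])[0]
        records = self.server.registry.taxonomy_query(name)
        payload = json.dumps([
            {"taxId": str(r.taxid), "scientificName": r.scientific_name,
             "rank": r.rank, "submittable": r.submittable}
            for r in records]).encode()
        self.send_response(200)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(payload)))
        self.end_headers()
        self.wfile.write(payload)

    def log_message(self, *args):  # keep test output quiet
        pass


class MockServiceServer:
    """Local HTTP front for the mock registry; binds an ephemeral port."""

    def __init__(self, registry: MockRegistry | None = None):
        self.registry = registry or MockRegistry()
        self.uploader = MockUploader(self.registry)
        self._server = ThreadingHTTPServer(("127.0.0.1", 0), _Handler)
        self._server.registry = self.registry
        self._server.uploader = self.uploader
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)

    @property
    def url(self) -> str:
        host, port = self._server.server_address
        return f"http://{host}:{port}"

    def __enter__(self):
        self._thread.start()
        return self

    def __exit__(self, *exc):
        self._server.shutdown()
        self._server.server_close()


class HttpRegistryClient:
    """Registry document endpoint over HTTP; raises TransportError on failure."""

    def __init__(self, base_url: str, auth_token: str | None = None):
        self.base_url = base_url.rstrip("/")
        self.auth_token = auth_token

    def _headers(self) -> dict:
        if self.auth_token is None:
            return {}
        return {"Authorization": f"Bearer {self.auth_token}"}

    def register(self, xml_text: str) -> str:
        req = urllib.request.Request(
            f"{self.base_url}/submit", data=xml_text.encode(),
            headers={"Content-Type": "application/xml", **self._headers()})
        try:
            with urllib.request.urlopen(req, timeout=30) as resp:
                return resp.read().decode()
        except urllib.error.URLError as exc:
            raise TransportError(f"registry endpoint unreachable: {exc}") from exc


class HttpUploadClient:
    """Upload-broker endpoint over HTTP: ships the staging location, gets a receipt."""

    def __init__(self, base_url: str, auth_token: str | None = None):
        self.base_url = base_url.rstrip("/")
        self.auth_token = auth_token

    def __call__(self, staged) -> Receipt:
        from .documents import parse_receipt
        body = json.dumps({"staging_dir": str(staged.staging_dir),
                           "level": staged.level.value}).encode()
        headers = {"Content-Type": "application/json"}
        if self.auth_token is not None:
            headers["Authorization"] = f"Bearer {self.auth_token}"
        req = urllib.request.Request(f"{self.base_url}/upload", data=body,
                                     headers=headers)
        try:
            with urllib.request.urlopen(req, timeout=30) as resp:
                return parse_receipt(resp.read().decode())
        except urllib.error.URLError as exc:
            raise TransportError(f"upload endpoint unreachable: {exc}") from exc


class HttpTaxonomyClient:
    """Taxonomy query endpoint over HTTP; same contract as the fixture client."""

    def __init__(self, base_url: str, auth_token: str | None = None):
        self.base_url = base_url.rstrip("/")
        self.auth_token = auth_token

    def query(self, name: str) -> list[TaxonRecord]:
        url = f"{self.base_url}/taxonomy?name={urllib.parse.quote(name)}"
        headers = {} if self.auth_token is None else \
            {"Authorization": f"Bearer {self.auth_token}"}
        try:
            with urllib.request.urlopen(
                    urllib.request.Request(url, headers=headers), timeout=30) as resp:
                raw = json.loads(resp.read().decode())
        except urllib.error.URLError as exc:
            raise TransportError(f"taxonomy endpoint unreachable: {exc}") from exc
        return [TaxonRecord(int(r["taxId"]), r["scientificName"], r.get("rank", ""),
                            bool(r.get("submittable"))) for r in raw]


# ---------------------------------------------------------------------------
# toy dataset generation

_QUALITY_TIERS = [(95.3, 2.1), (60.0, 5.0), (30.0, 15.0)]  # HIGH, MEDIUM, LOW
_LINEAGES = [
    "d__Bacteria;p__Pseudomonadota;c__Gammaproteobacteria;o__Enterobacterales;"
    "f__Enterobacteriaceae;g__;s__",
    "d__Archaea;p__Methanobacteriota;c__Methanococci;o__Methanococcales;"
    "f__Methanococcaceae;g__Methanococcus;s__",
    "d__Bacteria",
]
UNRESOLVABLE_LINEAGE = ("d__Bacteria;p__;c__;o__;f__Imaginariaceae;g__;s__")

_READ_LEN = 100
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _write_fasta(path: Path, records: list[tuple[str, str]]):
    with open(path, "w", newline="") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


@dataclass
class ToyDataset:
    """A generated miniature study plus the bookkeeping its tests rely on."""

    root: Path
    config_path: Path
    contig_lengths: dict[str, int]
    bin_contigs: dict[str, list[str]]
    total_aligned_bases: int = 0
    per_contig_aligned: dict[str, int] = field(default_factory=dict)

    @property
    def alignment_path(self) -> Path:
        return self.root / "alignment.sam"


def generate_toy_dataset(outdir: str | Path, seed: int = 7, n_samples: int = 2,
                         n_readpairs_per_sample: int = 20, n_bins: int = 3,
                         n_mags: int = 0, unresolvable_bin: bool = False) -> ToyDataset:
    """Write a seed-deterministic toy study into *outdir*.

    The dataset comprises per-sample paired FASTQ files of 100-base reads
    sampled from random contigs, a co-assembly FASTA over all samples, bin
    FASTAs partitioning disjoint contig subsets, a SAM placing every read
    perfectly (so coverage has a closed form), a CheckM-style quality table
    cycling through all three MIMAG tiers, a GTDB-style classification table
    (the family-level Enterobacteriaceae case, an archaeal genus, a
    domain-only lineage, and one unresolvable lineage), and a filled
    configuration that validates cleanly.  ``unresolvable_bin=True`` assigns
    the unresolvable lineage to the last configured bin instead of an
    unbinned genome, for halt-path testing.  Identical arguments produce
    byte-identical files.
    """
    if min(n_samples, n_readpairs_per_sample, n_bins) < 1:
        raise DatasetError("all size parameters must be positive")
    if n_mags > n_bins:
        raise DatasetError("cannot promote more MAGs than there are bins")
    root = Path(outdir)
    if root.exists() and any(root.iterdir()):
        raise DatasetError(f"target directory {root} exists and is not empty")
    rng = random.Random(seed)
    (root / "reads").mkdir(parents=True, exist_ok=True)
    (root / "bins").mkdir()

    n_contigs = 2 * n_bins + 2
    contigs: list[tuple[str, str]] = []
    for i in range(n_contigs):
        length = rng.randrange(240, 601)
        contigs.append((f"contig_{i + 1}",
                        "".join(rng.choice("ACGT") for _ in range(length))))
    contig_lengths = {name: len(seq) for name, seq in contigs}
    _write_fasta(root / "assembly.fasta", contigs)

    bin_contigs = {f"bin_{b + 1}": [contigs[2 * b][0], contigs[2 * b + 1][0]]
                   for b in range(n_bins)}
    for bin_id, names in bin_contigs.items():
        _write_fasta(root / "bins" / f"{bin_id}.fa",
                     [c for c in contigs if c[0] in names])
    (root / "mags").mkdir() if n_mags else None
    for m in range(n_mags):
        shutil.copyfile(root / "bins" / f"bin_{m + 1}.fa",
                        root / "mags" / f"mag_{m + 1}.fa")

    # reads + alignment map; every read aligns end-to-end, so the aligned
    # base count is exactly (number of read records) x read length
    sam_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    sam_lines += [f"@SQ\tSN:{name}\tLN:{length}"
                  for name, length in contig_lengths.items()]
    per_contig_aligned = {name: 0 for name in contig_lengths}
    qual = "I" * _READ_LEN
    for s in range(1, n_samples + 1):
        r1_path = root / "reads" / f"sample_{s}_R1.fastq"
        r2_path = root / "reads" / f"sample_{s}_R2.fastq"
        with open(r1_path, "w", newline="") as r1, open(r2_path, "w", newline="") as r2:
            for p in range(n_readpairs_per_sample):
                name, seq = contigs[rng.randrange(n_contigs)]
                pos1 = rng.randrange(0, len(seq) - _READ_LEN + 1)
                pos2 = rng.randrange(0, len(seq) - _READ_LEN + 1)
                frag1, frag2 = seq[pos1:pos1 + _READ_LEN], seq[pos2:pos2 + _READ_LEN]
                qname = f"s{s}_pair{p + 1}"
                r1.write(f"@{qname}/1\n{frag1}\n+\n{qual}\n")
                r2.write(f"@{qname}/2\n{_revcomp(frag2)}\n+\n{qual}\n")
                sam_lines.append("\t".join([
                    qname, "99", name, str(pos1 + 1), "60", f"{_READ_LEN}M",
                    "=", str(pos2 + 1), "0", frag1, qual]))
                sam_lines.append("\t".join([
                    qname, "147", name, str(pos2 + 1), "60", f"{_READ_LEN}M",
                    "=", str(pos1 + 1), "0", frag2, qual]))
                per_contig_aligned[name] += 2 * _READ_LEN
    (root / "alignment.sam").write_text("\n".join(sam_lines) + "\n", newline="")
    total_aligned = sum(per_contig_aligned.values())

    quality_rows = ["Bin Id\tCompleteness\tContamination"]
    taxonomy_rows = ["user_genome\tclassification"]
    bin_quality = {}
    for b in range(n_bins):
        bin_id = f"bin_{b + 1}"
        comp, cont = _QUALITY_TIERS[b % len(_QUALITY_TIERS)]
        bin_quality[bin_id] = (comp, cont)
        quality_rows.append(f"{bin_id}\t{comp}\t{cont}")
        lineage = _LINEAGES[b % len(_LINEAGES)]
        if unresolvable_bin and b == n_bins - 1:
            lineage = UNRESOLVABLE_LINEAGE
        taxonomy_rows.append(f"{bin_id}\t{lineage}")
    for m in range(n_mags):
        comp, cont = bin_quality[f"bin_{m + 1}"]
        quality_rows.append(f"mag_{m + 1}\t{comp}\t{cont}")
        taxonomy_rows.append(f"mag_{m + 1}\t{_LINEAGES[m % len(_LINEAGES)]}")
    if not unresolvable_bin:
        taxonomy_rows.append(f"unbinned_1\t{UNRESOLVABLE_LINEAGE}")
    (root / "quality.tsv").write_text("\n".join(quality_rows) + "\n", newline="")
    (root / "classification.tsv").write_text("\n".join(taxonomy_rows) + "\n",
                                             newline="")

    samples = []
    read_sets = []
    for s in range(1, n_samples + 1):
        sample = {
            "alias": f"sample_{s}",
            "title": f"toy sediment sample {s}",
            "scientific_name": "sediment metagenome",
            "taxid": 749907,
            "collection_date": "2023-06-14",
            "location": "Germany: Bielefeld",
        }
        if s == 1:
            sample["ph"] = "7.2"  # free extra attribute, preserved on parse
        samples.append(sample)
        read_sets.append({
            "alias": f"reads_sample_{s}",
            "sample_ref": f"sample_{s}",
            "platform": "ILLUMINA",
            "instrument": "Illumina HiSeq 2500",
            "library_layout": "PAIRED",
            "library_source": "METAGENOMIC",
            "library_selection": "RANDOM",
            "library_strategy": "WGS",
            "files": [f"reads/sample_{s}_R1.fastq", f"reads/sample_{s}_R2.fastq"],
        })
    doc = {
        "study": "PRJEB00001",
        "samples": samples,
        "read_sets": read_sets,
        "assembly": {
            "name": "toy_coassembly",
            "program": "metaSPAdes v3.15.5",
            "molecule_type": "genomic DNA",
            "sample_refs": [f"sample_{s}" for s in range(1, n_samples + 1)],
            "run_refs": [f"reads_sample_{s}" for s in range(1, n_samples + 1)],
            "fasta_path": "assembly.fasta",
        },
        "bins": [{
            "bin_id": f"bin_{b + 1}",
            "fasta_path": f"bins/bin_{b + 1}.fa",
            "binning_software": "MetaBAT 2.15",
        } for b in range(n_bins)],
        "aux": {
            "quality_table": "quality.tsv",
            "taxonomy_table": "classification.tsv",
            "alignment_map": "alignment.sam",
        },
    }
    if n_mags:
        doc["mags"] = [{
            "bin_id": f"mag_{m + 1}",
            "fasta_path": f"mags/mag_{m + 1}.fa",
            "binning_software": "MetaBAT 2.15",
            "derived_bin_id": f"bin_{m + 1}",
        } for m in range(n_mags)]
    config_path = root / "config.yaml"
    with open(config_path, "w", newline="") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)

    return ToyDataset(root, config_path, contig_lengths, bin_contigs,
                      total_aligned, per_contig_aligned)
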