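"""Shared fixtures: toy datasets, mock endpoints, scenario helpers."""

from __future__ import annotations

import random
from pathlib import Path

import pytest
import yaml

from mgbroker.config import load_config
from mgbroker.mock import MockRegistry, MockUploader, generate_toy_dataset
from mgbroker.model import Level, SubmissionScenario
from mgbroker.orchestrator import ServiceEndpoints

FULL_LEVELS = {Level.SAMPLES, Level.READS, Level.ASSEMBLY, Level.BINS}


def scenario(*levels: Level, preexisting=None) -> SubmissionScenario:
    return SubmissionScenario(frozenset(levels), preexisting or {})


@pytest.fixture
def toy(tmp_path):
    """Default toy study: 2 samples, 2 paired read sets, co-assembly, 3 bins."""
    return generate_toy_dataset(tmp_path / "toy", seed=7)


@pytest.fixture
def toy_config(toy):
    return load_config(toy.config_path)


@pytest.fixture
def mock_endpoints():
    """Factory for a fresh mock registry wired into service endpoints."""

    def make():
        registry = MockRegistry()
        endpoints = ServiceEndpoints(
            register=registry.register, taxonomy=registry.taxonomy,
            upload=MockUploader(registry), retry_wait=0.0)
        return registry, endpoints

    return make


def write_sam(path: Path, contigs: dict[str, int], records: list[str]) -> Path:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{n}\tLN:{l}" for n, l in contigs.items()]
    lines += records
    path.write_text("\n".join(lines) + "\n")
    return path


def sam_record(qname: str, contig: str, pos1: int, cigar: str, flag: int = 0,
               seq_len: int = 10) -> str:
    seq = "A" * seq_len
    return "\t".join([qname, str(flag), contig, str(pos1), "60", cigar,
                      "*", "0", "0", seq, "I" * seq_len])


_CIGAR_REF_OPS = set("MDX=")
_CIGAR_READ_OPS = set("MIS=X")


def random_sam(path: Path, rng: random.Random) -> Path:
    """A randomized toy alignment map with decoy records the counters must skip."""
    contigs = {f"c{i}": rng.randrange(50, 400) for i in range(rng.randrange(1, 5))}
    names = list(contigs)
    records = []
    for r in range(rng.randrange(0, 25)):
        contig = rng.choice(names)
        ops = []
        ref_span = 0
        for _ in range(rng.randrange(1, 4)):
            op = rng.choice("MMMMIDS=X")
            length = rng.randrange(1, 30)
            ops.append(f"{length}{op}")
            if op in _CIGAR_REF_OPS:
                ref_span += length
        if ref_span == 0 or ref_span > contigs[contig]:
            continue
        pos = rng.randrange(1, contigs[contig] - ref_span + 2)
        flag = rng.choice([0, 0, 0, 16, 256, 2048, 4])
        read_len = sum(int(o[:-1]) for o in ops if o[-1] in _CIGAR_READ_OPS)
        if read_len == 0:  # CIGAR without read-consuming ops is not a record
            continue
        cigar = "".join(ops)
        if flag == 4:
            records.append("\t".join(["q%d" % r, "4", "*", "0", "0", "*", "*",
                                      "0", "0", "A" * read_len, "I" * read_len]))
        else:
            records.append("\t".join(["q%d" % r, str(flag), contig, str(pos),
                                      "60", cigar, "*", "0", "0",
                                      "A" * read_len, "I" * read_len]))
    return write_sam(path, contigs, records)


def brute_force_depth(path: Path) -> tuple[int, int]:
    """Independent per-position depth oracle from the SAM text itself.

    Returns (total depth summed over every reference position, total
    reference length).  Counts primary mapped records only, walking the
    CIGAR position by position.
    """
    import re

    contigs: dict[str, int] = {}
    depth: dict[str, list[int]] = {}
    for line in path.read_text().splitlines():
        if line.startswith("@"):
            if line.startswith("@SQ"):
                fields = dict(f.split(":", 1) for f in line.split("\t")[1:])
                contigs[fields["SN"]] = int(fields["LN"])
                depth[fields["SN"]] = [0] * int(fields["LN"])
            continue
        cols = line.split("\t")
        flag = int(cols[1])
        if flag & (0x4 | 0x100 | 0x800):  # unmapped / secondary / supplementary
            continue
        contig, pos, cigar = cols[2], int(cols[3]) - 1, cols[5]
        for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
            length = int(length)
            if op in "MDX=":
                for p in range(pos, pos + length):
                    depth[contig][p] += 1
                pos += length
    return sum(map(sum, depth.values())), sum(contigs.values())


def scenario_config_doc(toy_ds, levels: set[Level],
                        preexisting: dict | None = None) -> dict:
    """Subset the toy study's configuration to one scenario's sections."""
    doc = yaml.safe_load(toy_ds.config_path.read_text())
    out = {"study": doc["study"]}
    preexisting = preexisting or {}
    if Level.SAMPLES in levels:
        out["samples"] = doc["samples"]
    elif Level.SAMPLES in preexisting:
        out["known_sample_accessions"] = list(preexisting[Level.SAMPLES])
    if Level.READS in levels:
        out["read_sets"] = doc["read_sets"]
        if Level.SAMPLES not in levels and Level.SAMPLES in preexisting:
            for rs, acc in zip(out["read_sets"], preexisting[Level.SAMPLES]):
                rs["sample_ref"] = acc
    elif Level.READS in preexisting:
        out["known_run_accessions"] = list(preexisting[Level.READS])
    if Level.ASSEMBLY in levels:
        out["assembly"] = doc["assembly"]
        if Level.SAMPLES not in levels and Level.SAMPLES in preexisting:
            out["assembly"]["sample_refs"] = list(preexisting[Level.SAMPLES])
        if Level.READS not in levels:
            out["assembly"]["run_refs"] = list(preexisting.get(Level.READS, []))
    elif Level.ASSEMBLY in preexisting:
        out["known_assembly_accession"] = preexisting[Level.ASSEMBLY][0]
    if Level.BINS in levels:
        out["bins"] = doc["bins"]
    if Level.MAGS in levels:
        out["mags"] = doc["mags"]
    if Level.ASSEMBLY in levels or Level.BINS in levels or Level.MAGS in levels:
        out["aux"] = doc["aux"]
    return out
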