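"""Readers for third-party pipeline outputs and derived quantities.

Bin quality comes from CheckM-style tab-separated tables, taxonomic
classifications from GTDB-Tk-style summaries, and fold coverage from SAM/BAM
alignment maps.  This module ingests those formats and derives the two
quantities the submission needs per genome: a MIMAG quality tier and a fold
coverage value.

Fold coverage is defined here as the number of aligned reference-consuming
bases (CIGAR M/=/X/D of primary, mapped, non-supplementary records) divided by
the total length of the counted reference sequences.  Deletions consume
reference and are counted; soft/hard clips and insertions are not.  This makes
the value exactly reproducible by a per-position depth pileup.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .errors import (
    ConflictError,
    CoverageInputError,
    HeaderError,
    LineageDialectError,
    TableRangeError,
)
from .model import QualityStats

CANONICAL_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_GTDB_PREFIXES = {"d": 0, "p": 1, "c": 2, "o": 3, "f": 4, "g": 5, "s": 6}

# Header synonyms, lowercase. CheckM writes "Bin Id", CheckM2 "Name",
# GTDB-Tk "user_genome".
_BIN_ID_HEADERS = {"bin id", "bin_id", "name", "user_genome", "genome", "genome id"}
_COMPLETENESS_HEADERS = {"completeness"}
_CONTAMINATION_HEADERS = {"contamination"}
_CLASSIFICATION_HEADERS = {"classification", "taxonomy", "lineage"}


class MimagTier(str, Enum):
    HIGH = "HIGH"
    MEDIUM = "MEDIUM"
    LOW = "LOW"


def classify_mimag(q: QualityStats) -> MimagTier:
    """MIMAG quality tier from completeness/contamination percentages.

    High quality: completeness > 90 and contamination < 5.  Medium quality:
    completeness >= 50 and contamination < 10.  Everything else is low
    quality.  The rRNA/tRNA presence criteria of the full standard are out of
    scope here (they require gene calling).
    """
    if q.completeness > 90.0 and q.contamination < 5.0:
        return MimagTier.HIGH
    if q.completeness >= 50.0 and q.contamination < 10.0:
        return MimagTier.MEDIUM
    return MimagTier.LOW


def _find_column(columns: Iterable[str], synonyms: set[str], what: str) -> str:
    for col in columns:
        if col.strip().lower() in synonyms:
            return col
    raise HeaderError(
        f"no {what} column found; table columns are: {', '.join(columns)}")


def read_quality_table(path: str | Path) -> dict[str, QualityStats]:
    """Parse a CheckM-style TSV into per-bin completeness/contamination."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = _find_column(df.columns, _BIN_ID_HEADERS, "bin-identifier")
    comp_col = _find_column(df.columns, _COMPLETENESS_HEADERS, "completeness")
    cont_col = _find_column(df.columns, _CONTAMINATION_HEADERS, "contamination")
    out: dict[str, QualityStats] = {}
    for i, row in df.iterrows():
        bin_id = str(row[id_col]).strip()
        try:
            stats = QualityStats(float(row[comp_col]), float(row[cont_col]))
        except ValueError as exc:
            raise TableRangeError(f"{path}, row {i + 2} ({bin_id}): {exc}") from exc
        if bin_id in out:
            raise ConflictError(f"{path}: duplicate bin id {bin_id!r}")
        out[bin_id] = stats
    return out


def read_taxonomy_table(path: str | Path) -> dict[str, str]:
    """Parse a GTDB-Tk-style summary into raw classification strings, verbatim."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = _find_column(df.columns, _BIN_ID_HEADERS, "genome-identifier")
    cls_col = _find_column(df.columns, _CLASSIFICATION_HEADERS, "classification")
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        bin_id = str(row[id_col]).strip()
        if bin_id in out:
            raise ConflictError(f"{path}: duplicate genome id {bin_id!r}")
        out[bin_id] = str(row[cls_col])
    return out


@dataclass
class RankedLineage:
    """A classification normalized onto the seven canonical ranks.

    Empty strings mark unclassified ranks; polyphyletic suffixes of the GTDB
    reference taxonomy (``Escherichia_B`` style) are stripped, with a note,
    because taxonomy-registry records use base names.
    """

    names: tuple[str, ...]  # always length 7, domain..species
    source_dialect: str     # "GTDB" | "NCBI-semicolon"
    notes: list[str] = field(default_factory=list)

    @property
    def domain(self) -> str:
        return self.names[0]

    def rank(self, name: str) -> str:
        return self.names[CANONICAL_RANKS.index(name)]

    def lowest(self) -> tuple[str, str] | None:
        """(rank label, name) of the most specific classified rank, or None."""
        for i in range(6, -1, -1):
            if self.names[i]:
                return CANONICAL_RANKS[i], self.names[i]
        return None

    def to_string(self) -> str:
        if self.source_dialect == "GTDB":
            return ";".join(f"{p}__{n}" for p, n in zip("dpcofgs", self.names))
        last = max((i for i, n in enumerate(self.names) if n), default=-1)
        return ";".join(self.names[: last + 1])


def _strip_polyphyletic_suffix(name: str) -> tuple[str, bool]:
    # Suffix applies to the trailing whitespace token only ("Escherichia coli_D").
    parts = name.split(" ")
    stripped = re.sub(r"_[A-Z]+$", "", parts[-1])
    if stripped != parts[-1] and stripped:
        return " ".join(parts[:-1] + [stripped]), True
    return name, False


def parse_lineage(raw: str) -> RankedLineage:
    """Parse a classification string in GTDB prefix dialect or plain semicolon form."""
    tokens = [t.strip() for t in raw.strip().split(";")] if raw.strip() else []
    names = [""] * 7
    notes: list[str] = []
    if any("__" in t for t in tokens):
        dialect = "GTDB"
        for token in tokens:
            if not token:
                continue
            prefix, _, name = token.partition("__")
            if prefix not in _GTDB_PREFIXES:
                raise LineageDialectError(
                    f"unrecognized rank prefix {prefix!r} in {token!r}")
            names[_GTDB_PREFIXES[prefix]] = name.strip()
    else:
        dialect = "NCBI-semicolon"
        if len(tokens) > 7:
            raise LineageDialectError(
                f"{len(tokens)} ranks given; at most 7 canonical ranks supported")
        for i, token in enumerate(tokens):
            names[i] = token
    for i, name in enumerate(names):
        if not name:
            continue
        stripped, changed = _strip_polyphyletic_suffix(name)
        if changed:
            notes.append(
                f"{CANONICAL_RANKS[i]}: normalized {name!r} -> {stripped!r} "
                "(polyphyletic suffix)")
            names[i] = stripped
    return RankedLineage(tuple(names), dialect, notes)


@dataclass
class CoverageStats:
    aligned_bases: int
    reference_length: int

    def __post_init__(self):
        if self.reference_length <= 0:
            raise ValueError("reference length must be positive")
        if self.aligned_bases < 0:
            raise ValueError("aligned bases cannot be negative")

    @property
    def fold(self) -> float:
        return self.aligned_bases / self.reference_length


_REF_CONSUMING_OPS = {0, 2, 7, 8}  # M, D, =, X


def compute_coverage(alignment_path: str | Path,
                     restrict_to: set[str] | None = None) -> CoverageStats:
    """Fold coverage from a SAM/BAM alignment map.

    ``restrict_to`` limits both the counted alignments and the reference
    length to the named contigs — this is how per-bin coverage is derived from
    an assembly-wide map.
    """
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        refs: Mapping[str, int] = dict(zip(af.references, af.lengths))
        if not refs:
            raise CoverageInputError(
                f"{alignment_path}: header declares no reference sequences")
        if restrict_to is not None:
            unknown = set(restrict_to) - set(refs)
            if unknown:
                raise CoverageInputError(
                    f"{alignment_path}: contigs not in header: {sorted(unknown)}")
            counted = {r: refs[r] for r in restrict_to}
        else:
            counted = dict(refs)
        aligned = 0
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name not in counted:
                continue
            aligned += sum(l for op, l in rec.cigartuples or []
                           if op in _REF_CONSUMING_OPS)
    return CoverageStats(aligned, sum(counted.values()))


def fasta_contig_names(path: str | Path) -> list[str]:
    """Contig names from a FASTA file (first whitespace token of each header)."""
    names = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                names.append(line[1:].split()[0])
    return names
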