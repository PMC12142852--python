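"""Domain types shared by every stage of the submission workflow.

A metagenomics deposition touches many registry objects — samples, sequencing
runs, assemblies, binned contigs, and metagenome-assembled genomes (MAGs) —
each of which receives a stable accession that downstream steps must
reference.  The types here model those objects, the submission scenario (which
data levels are being deposited, and which are covered by accessions from a
previous deposition), and the accession ledger that threads assigned
identifiers through the dependency-ordered steps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, NamedTuple, Sequence

from .errors import (
    AccessionFormatError,
    ConflictError,
    ScenarioError,
    UnresolvedReferenceError,
)


class Level(str, Enum):
    """Data levels of a metagenomics deposition."""

    SAMPLES = "SAMPLES"
    READS = "READS"
    ASSEMBLY = "ASSEMBLY"
    BINS = "BINS"
    MAGS = "MAGS"


class ObjectKind(str, Enum):
    """Registry object kinds that receive accessions."""

    SAMPLE = "SAMPLE"
    RUN = "RUN"
    ANALYSIS = "ANALYSIS"
    STUDY = "STUDY"


# Public INSDC-style accession shapes.  The mock registry issues accessions of
# exactly these shapes so that ledger validation is exercised for real; the
# table is passed around explicitly so alternative registries can override it.
DEFAULT_ACCESSION_PATTERNS: dict[ObjectKind, re.Pattern] = {
    ObjectKind.SAMPLE: re.compile(r"(ERS|SAMEA)\d+$"),
    ObjectKind.RUN: re.compile(r"ERR\d+$"),
    ObjectKind.ANALYSIS: re.compile(r"ERZ\d+$"),
    ObjectKind.STUDY: re.compile(r"(PRJ[EDN][A-Z]\d+|ERP\d+)$"),
}


def matches_accession(ref: str, kind: ObjectKind | None = None,
                      patterns: Mapping[ObjectKind, re.Pattern] | None = None) -> bool:
    """True if *ref* looks like an accession (of *kind*, or of any kind)."""
    patterns = patterns or DEFAULT_ACCESSION_PATTERNS
    kinds = [kind] if kind is not None else list(patterns)
    return any(patterns[k].fullmatch(ref) for k in kinds)


@dataclass(frozen=True)
class SubmissionScenario:
    """The set of data levels to submit, plus accessions of levels already deposited.

    ``preexisting`` maps a level to the accessions assigned in an earlier
    deposition; such levels produce no submission steps but seed the ledger,
    which is how an existing study is extended.
    """

    levels: frozenset[Level]
    preexisting: Mapping[Level, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "levels", frozenset(self.levels))
        object.__setattr__(
            self, "preexisting",
            {Level(k): tuple(v) for k, v in dict(self.preexisting).items()},
        )

    def covered(self, level: Level) -> bool:
        """A level is covered if it is being submitted or has preexisting accessions."""
        return level in self.levels or bool(self.preexisting.get(level))

    def validate(self) -> None:
        if not self.levels:
            raise ScenarioError("scenario has no data levels")
        if (Level.BINS in self.levels or Level.MAGS in self.levels) \
                and not self.covered(Level.ASSEMBLY):
            raise ScenarioError(
                "bins/MAGs require an assembly level or a preexisting assembly accession")
        if Level.READS in self.levels and not self.covered(Level.SAMPLES):
            raise ScenarioError(
                "reads require a samples level or preexisting sample accessions")


@dataclass
class SampleRecord:
    alias: str
    title: str
    scientific_name: str
    taxid: int
    collection_date: str
    location: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.taxid = int(self.taxid)
        if self.taxid <= 0:
            raise ValueError(f"sample {self.alias!r}: taxid must be positive")


@dataclass
class ReadSetRecord:
    alias: str
    sample_ref: str
    platform: str
    instrument: str
    library_layout: str  # SINGLE | PAIRED
    library_source: str
    library_selection: str
    library_strategy: str
    files: list[str]
    checksums: list[str] | None = None
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class QualityStats:
    """Genome completeness/contamination estimates, as percentages."""

    completeness: float
    contamination: float

    def __post_init__(self):
        self.completeness = float(self.completeness)
        self.contamination = float(self.contamination)
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"completeness {self.completeness} outside [0, 100]")
        if self.contamination < 0.0:
            raise ValueError(f"contamination {self.contamination} negative")


@dataclass
class TaxonomyAssignment:
    """A resolved environmental taxon for a bin/MAG/co-assembly sample object."""

    scientific_name: str
    taxid: int
    source: str = "RESOLVED"  # USER | RESOLVED
    rank_used: str = "NONE"

    def __post_init__(self):
        self.taxid = int(self.taxid)
        if self.taxid <= 0:
            raise ValueError("taxid must be a positive integer")
        if self.source not in ("USER", "RESOLVED"):
            raise ValueError(f"unknown assignment source {self.source!r}")


@dataclass
class AssemblyRecord:
    name: str
    program: str
    sample_refs: list[str]
    run_refs: list[str]
    fasta_path: str
    molecule_type: str
    coverage: float | None = None  # None = infer from the alignment map
    platform: str | None = None   # None = derive from referenced read sets
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sample_refs:
            raise ValueError(f"assembly {self.name!r}: at least one sample ref required")
        if self.coverage is not None and float(self.coverage) < 0:
            raise ValueError(f"assembly {self.name!r}: coverage must be >= 0")

    @property
    def is_coassembly(self) -> bool:
        return len(self.sample_refs) > 1


@dataclass
class BinRecord:
    bin_id: str
    fasta_path: str
    binning_software: str
    quality: QualityStats | None = None
    lineage: str | None = None  # raw classification string
    taxonomy_override: TaxonomyAssignment | None = None
    coverage: float | None = None
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class MagRecord(BinRecord):
    """A bin promoted to a metagenome-assembled genome.

    Quality below the MIMAG high-quality bar is advisory (a validation
    WARNING), never an error.
    """

    derived_bin_id: str | None = None
    mag_flag: bool = True


class Assignment(NamedTuple):
    kind: ObjectKind
    alias: str
    accession: str


@dataclass
class Receipt:
    """Parsed registry response: success state, accession assignments, messages."""

    success: bool
    assignments: list[Assignment] = field(default_factory=list)
    messages: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.success and self.assignments:
            raise ValueError("a failure receipt cannot carry accession assignments")
        for a in self.assignments:
            if not a.alias or not a.accession:
                raise ValueError("assignments must have nonempty alias and accession")

    @property
    def errors(self) -> list[str]:
        return [t for s, t in self.messages if s.upper() == "ERROR"]


@dataclass(frozen=True)
class TaxonRecord:
    """One taxonomy-registry record; only submittable records may back a resolution."""

    taxid: int
    scientific_name: str
    rank: str
    submittable: bool


class LedgerEntry(NamedTuple):
    accession: str
    kind: ObjectKind
    step_index: int


class AccessionLedger:
    """Alias → accession map driving downstream object references.

    Aliases are write-once; entries remember their insertion step so a run
    summary reconstructs the submission order.  ``resolve`` accepts either a
    known alias or an accession literal (anything matching the pattern table
    passes through unchanged), which lets configuration fields reference
    previously deposited objects directly.
    """

    def __init__(self, patterns: Mapping[ObjectKind, re.Pattern] | None = None):
        self.patterns = dict(patterns or DEFAULT_ACCESSION_PATTERNS)
        self._entries: dict[str, LedgerEntry] = {}

    def add(self, alias: str, kind: ObjectKind, accession: str,
            step_index: int | None = None) -> "AccessionLedger":
        kind = ObjectKind(kind)
        if alias in self._entries:
            raise ConflictError(f"alias {alias!r} already holds an accession")
        if not self.patterns[kind].fullmatch(accession):
            raise AccessionFormatError(
                f"{accession!r} does not match the {kind.value} accession pattern "
                f"{self.patterns[kind].pattern!r}")
        if step_index is None:
            step_index = len(self._entries)
        self._entries[alias] = LedgerEntry(accession, kind, step_index)
        return self

    def resolve(self, ref: str) -> str:
        if ref in self._entries:
            return self._entries[ref].accession
        if matches_accession(ref, patterns=self.patterns):
            return ref
        raise UnresolvedReferenceError(
            f"{ref!r} is neither a recorded alias nor an accession literal")

    def __contains__(self, alias: str) -> bool:
        return alias in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, alias: str) -> LedgerEntry:
        return self._entries[alias]

    def items(self) -> Iterator[tuple[str, LedgerEntry]]:
        return iter(sorted(self._entries.items(), key=lambda kv: kv[1].step_index))

    def aliases(self) -> list[str]:
        return [a for a, _ in self.items()]
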