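"""Scenario-driven configuration templating, parsing and validation.

The whole submission is described by one YAML document.  ``make_template``
writes a scenario-specific skeleton containing only the fields mandatory for
the requested data levels, each preceded by a comment explaining what is
required, with an example.  Levels already deposited in an earlier submission
are represented by accession-entry fields instead of metadata sections.

``parse_config`` materializes the filled document into records; any key the
schema does not know is preserved as an additional attribute, so users can
enrich their metadata freely.  ``validate_config`` checks the document and
every referenced file before any submission step and reports all problems at
once; errors block submission, warnings never do.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .errors import ConfigParseError, FieldError
from .model import (
    AssemblyRecord,
    BinRecord,
    DEFAULT_ACCESSION_PATTERNS,
    Level,
    MagRecord,
    ObjectKind,
    QualityStats,
    ReadSetRecord,
    SampleRecord,
    SubmissionScenario,
    TaxonomyAssignment,
    matches_accession,
)
from .readers import MimagTier, classify_mimag, read_quality_table

# ---------------------------------------------------------------------------
# field tables: (key, example, explanation); the same tables drive template
# rendering, parsing and validation, so the three can never drift apart.

_SAMPLE_FIELDS = (
    ("alias", "sample_1", "Unique name for this sample within the study"),
    ("title", "sediment core, station 1", "Short human-readable sample title"),
    ("scientific_name", "sediment metagenome",
     "Scientific name of the sampled metagenome taxon"),
    ("taxid", "749907", "Taxonomy identifier matching the scientific name"),
    ("collection_date", "2023-06-14",
     "ISO-8601 collection date, or the keyword 'missing'"),
    ("location", "Germany: Bielefeld",
     "Geographic origin (country/sea), or the keyword 'missing'"),
)
_READ_FIELDS = (
    ("alias", "reads_sample_1", "Unique name for this sequencing run"),
    ("sample_ref", "sample_1",
     "Sample this run derives from: an alias above, or a sample accession"),
    ("platform", "ILLUMINA", "Sequencing platform"),
    ("instrument", "Illumina HiSeq 2500", "Instrument model"),
    ("library_layout", "PAIRED", "SINGLE or PAIRED"),
    ("library_source", "METAGENOMIC", "Library source"),
    ("library_selection", "RANDOM", "Library selection method"),
    ("library_strategy", "WGS", "Library strategy"),
    ("files", "[reads_1.fastq, reads_2.fastq]",
     "FASTQ file path(s): one for SINGLE, exactly two for PAIRED"),
)
_ASSEMBLY_FIELDS = (
    ("name", "coassembly_1", "Assembly name, unique within the study"),
    ("program", "metaSPAdes v3.15.5", "Assembler name and version"),
    ("molecule_type", "genomic DNA", "Molecule type of the assembly"),
    ("sample_refs", "[sample_1, sample_2]",
     "Samples assembled together (aliases or accessions); more than one marks a co-assembly"),
    ("run_refs", "[reads_sample_1, reads_sample_2]",
     "Sequencing runs used (aliases or run accessions)"),
    ("fasta_path", "assembly.fasta", "Path to the assembly FASTA"),
)
_BIN_FIELDS = (
    ("bin_id", "bin_1",
     "Bin identifier; must match the quality/classification tables"),
    ("fasta_path", "bins/bin_1.fa", "Path to the bin FASTA"),
    ("binning_software", "MetaBAT 2", "Binning software name and version"),
)
_AUX_FIELDS = (
    ("quality_table", "checkm_quality.tsv",
     "CheckM-style TSV with completeness/contamination per bin"),
    ("taxonomy_table", "gtdbtk_classification.tsv",
     "GTDB-Tk-style TSV with a classification string per bin"),
    ("alignment_map", "alignment.sam",
     "SAM/BAM of reads against the assembly, used to infer missing coverage"),
)

_MANDATORY_KEYS = {
    "sample": tuple(k for k, _, _ in _SAMPLE_FIELDS),
    "read_set": tuple(k for k, _, _ in _READ_FIELDS),
    "assembly": tuple(k for k, _, _ in _ASSEMBLY_FIELDS),
    "bin": tuple(k for k, _, _ in _BIN_FIELDS),
}
_OPTIONAL_KEYS = {
    "sample": ("attributes",),
    "read_set": ("checksums", "attributes"),
    "assembly": ("coverage", "platform", "attributes"),
    "bin": ("coverage", "taxonomy_override", "derived_bin_id", "attributes"),
}

MISSING_KEYWORD = "missing"
_ISO_DATE = re.compile(r"\d{4}(-\d{2}(-\d{2}([T ].*)?)?)?$")
_MD5_HEX = re.compile(r"[0-9a-fA-F]{32}$")


@dataclass
class AuxPaths:
    quality_table: str | None = None
    taxonomy_table: str | None = None
    alignment_maps: list[str] = field(default_factory=list)


@dataclass
class SubmissionConfig:
    """The single consolidated metadata document for one study's submission."""

    study_ref: str
    samples: list[SampleRecord] = field(default_factory=list)
    read_sets: list[ReadSetRecord] = field(default_factory=list)
    assembly: AssemblyRecord | None = None
    bins: list[BinRecord] = field(default_factory=list)
    mags: list[MagRecord] = field(default_factory=list)
    aux: AuxPaths = field(default_factory=AuxPaths)
    preexisting: dict[Level, tuple[str, ...]] = field(default_factory=dict)
    extras: dict[str, Any] = field(default_factory=dict)

    def sample_aliases(self) -> set[str]:
        return {s.alias for s in self.samples}

    def read_aliases(self) -> set[str]:
        return {r.alias for r in self.read_sets}

    def bin_ids(self) -> set[str]:
        return {b.bin_id for b in self.bins}

    def all_genomes(self) -> list[BinRecord]:
        return [*self.bins, *self.mags]


@dataclass
class ValidationIssue:
    severity: str  # ERROR | WARNING
    locus: str     # dotted field path, e.g. read_sets.0.files
    message: str

    def __str__(self) -> str:
        return f"{self.severity} {self.locus}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "ERROR"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "WARNING"]

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# template generation


def _render_fields(fields, indent: int, first_dash: bool) -> list[str]:
    pad = " " * indent
    lines = []
    for i, (key, example, comment) in enumerate(fields):
        lines.append(f"{pad}# {comment} (example: {example})")
        prefix = f"{' ' * (indent - 2)}- " if first_dash and i == 0 else pad
        lines.append(f"{prefix}{key}:")
    return lines


def make_template(scenario: SubmissionScenario) -> str:
    """Scenario-specific configuration skeleton with only the mandatory fields.

    Levels carried by preexisting accessions get accession-entry fields
    (pre-filled with the accessions named in the scenario) instead of a
    metadata section.
    """
    scenario.validate()
    lines = [
        "# Submission configuration — fill every field below.",
        "# Additional metadata keys may be added to any record at your discretion;",
        "# they are preserved and submitted as extra attributes.",
        "",
        "# Accession of the study this submission belongs to (example: PRJEB00001)",
        "study:",
        "",
    ]
    if Level.SAMPLES in scenario.levels:
        lines += ["samples:"] + _render_fields(_SAMPLE_FIELDS, 4, True) + [""]
    elif scenario.preexisting.get(Level.SAMPLES):
        lines += ["# Accessions of the previously deposited samples",
                  "known_sample_accessions:"]
        lines += [f"  - {acc}" for acc in scenario.preexisting[Level.SAMPLES]]
        lines += [""]
    if Level.READS in scenario.levels:
        lines += ["read_sets:"] + _render_fields(_READ_FIELDS, 4, True) + [""]
    elif scenario.preexisting.get(Level.READS):
        lines += ["# Accessions of the previously deposited sequencing runs",
                  "known_run_accessions:"]
        lines += [f"  - {acc}" for acc in scenario.preexisting[Level.READS]]
        lines += [""]
    if Level.ASSEMBLY in scenario.levels:
        lines += ["assembly:"] + _render_fields(_ASSEMBLY_FIELDS, 2, False) + [""]
    elif scenario.preexisting.get(Level.ASSEMBLY):
        acc = scenario.preexisting[Level.ASSEMBLY][0]
        lines += ["# Accession of the previously deposited assembly",
                  f"known_assembly_accession: {acc}", ""]
    if Level.BINS in scenario.levels:
        lines += ["bins:"] + _render_fields(_BIN_FIELDS, 4, True) + [""]
    if Level.MAGS in scenario.levels:
        mag_fields = _BIN_FIELDS + (
            ("derived_bin_id", "bin_1",
             "Identifier of the source bin, if the MAG derives from a submitted bin"),)
        lines += ["mags:"] + _render_fields(mag_fields, 4, True) + [""]
    if Level.BINS in scenario.levels or Level.MAGS in scenario.levels \
            or Level.ASSEMBLY in scenario.levels:
        aux_fields = _AUX_FIELDS if (Level.BINS in scenario.levels
                                     or Level.MAGS in scenario.levels) \
            else _AUX_FIELDS[2:]
        lines += ["aux:"] + _render_fields(aux_fields, 2, False) + [""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# parsing


def _require(mapping: Mapping, key: str, path: str):
    if key not in mapping or mapping[key] is None:
        raise FieldError(f"{path}.{key}", "mandatory field missing")
    return mapping[key]


def _split_extras(mapping: Mapping, kind: str, path: str) -> dict[str, str]:
    known = set(_MANDATORY_KEYS[kind]) | set(_OPTIONAL_KEYS[kind])
    extras = {str(k): str(v) for k, v in mapping.items()
              if k not in known and v is not None}
    declared = mapping.get("attributes") or {}
    if not isinstance(declared, Mapping):
        raise FieldError(f"{path}.attributes", "must be a key/value mapping")
    extras.update({str(k): str(v) for k, v in declared.items()})
    return extras


def _as_list(value) -> list:
    if value is None:
        return []
    return list(value) if isinstance(value, (list, tuple)) else [value]


def _parse_override(raw, path: str) -> TaxonomyAssignment | None:
    if raw is None:
        return None
    if not isinstance(raw, Mapping) or "scientific_name" not in raw or "taxid" not in raw:
        raise FieldError(path, "taxonomy_override needs scientific_name and taxid")
    return TaxonomyAssignment(str(raw["scientific_name"]), int(raw["taxid"]),
                              source="USER")


def _parse_bin(raw: Mapping, path: str, mag: bool) -> BinRecord:
    kwargs = dict(
        bin_id=str(_require(raw, "bin_id", path)),
        fasta_path=str(_require(raw, "fasta_path", path)),
        binning_software=str(_require(raw, "binning_software", path)),
        coverage=None if raw.get("coverage") is None else float(raw["coverage"]),
        taxonomy_override=_parse_override(raw.get("taxonomy_override"),
                                          f"{path}.taxonomy_override"),
        extras=_split_extras(raw, "bin", path),
    )
    if mag:
        did = raw.get("derived_bin_id")
        return MagRecord(**kwargs, derived_bin_id=None if did is None else str(did))
    return BinRecord(**kwargs)


def parse_config(text: str) -> SubmissionConfig:
    """Materialize a filled configuration document.

    Unknown keys under any record are preserved in its attributes, so users
    can add metadata beyond the mandatory fields.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        raise ConfigParseError(str(getattr(exc, "problem", exc)),
                               None if mark is None else mark.line + 1)
    if doc is None:
        raise ConfigParseError("empty configuration document")
    if not isinstance(doc, Mapping):
        raise ConfigParseError("configuration must be a key/value document")

    study = doc.get("study")
    if study is None:
        raise FieldError("study", "mandatory field missing")

    samples = []
    for i, raw in enumerate(_as_list(doc.get("samples"))):
        path = f"samples.{i}"
        try:
            samples.append(SampleRecord(
                alias=str(_require(raw, "alias", path)),
                title=str(_require(raw, "title", path)),
                scientific_name=str(_require(raw, "scientific_name", path)),
                taxid=int(_require(raw, "taxid", path)),
                collection_date=str(_require(raw, "collection_date", path)),
                location=str(_require(raw, "location", path)),
                attributes=_split_extras(raw, "sample", path),
            ))
        except (TypeError, ValueError) as exc:
            raise FieldError(path, str(exc))

    read_sets = []
    for i, raw in enumerate(_as_list(doc.get("read_sets"))):
        path = f"read_sets.{i}"
        checksums = raw.get("checksums")
        read_sets.append(ReadSetRecord(
            alias=str(_require(raw, "alias", path)),
            sample_ref=str(_require(raw, "sample_ref", path)),
            platform=str(_require(raw, "platform", path)),
            instrument=str(_require(raw, "instrument", path)),
            library_layout=str(_require(raw, "library_layout", path)).upper(),
            library_source=str(_require(raw, "library_source", path)),
            library_selection=str(_require(raw, "library_selection", path)),
            library_strategy=str(_require(raw, "library_strategy", path)),
            files=[str(f) for f in _as_list(_require(raw, "files", path))],
            checksums=None if checksums is None else [str(c) for c in checksums],
            extras=_split_extras(raw, "read_set", path),
        ))

    assembly = None
    if doc.get("assembly") is not None:
        raw, path = doc["assembly"], "assembly"
        try:
            assembly = AssemblyRecord(
                name=str(_require(raw, "name", path)),
                program=str(_require(raw, "program", path)),
                molecule_type=str(_require(raw, "molecule_type", path)),
                sample_refs=[str(s) for s in _as_list(_require(raw, "sample_refs", path))],
                run_refs=[str(r) for r in _as_list(raw.get("run_refs"))],
                fasta_path=str(_require(raw, "fasta_path", path)),
                coverage=None if raw.get("coverage") is None else float(raw["coverage"]),
                platform=None if raw.get("platform") is None else str(raw["platform"]),
                extras=_split_extras(raw, "assembly", path),
            )
        except (TypeError, ValueError) as exc:
            raise FieldError(path, str(exc))

    bins = [_parse_bin(raw, f"bins.{i}", mag=False)
            for i, raw in enumerate(_as_list(doc.get("bins")))]
    mags = [_parse_bin(raw, f"mags.{i}", mag=True)
            for i, raw in enumerate(_as_list(doc.get("mags")))]

    aux_raw = doc.get("aux") or {}
    aux = AuxPaths(
        quality_table=aux_raw.get("quality_table"),
        taxonomy_table=aux_raw.get("taxonomy_table"),
        alignment_maps=[str(p) for p in _as_list(aux_raw.get("alignment_map"))],
    )

    preexisting: dict[Level, tuple[str, ...]] = {}
    if doc.get("known_sample_accessions"):
        preexisting[Level.SAMPLES] = tuple(str(a) for a in doc["known_sample_accessions"])
    if doc.get("known_run_accessions"):
        preexisting[Level.READS] = tuple(str(a) for a in doc["known_run_accessions"])
    if doc.get("known_assembly_accession"):
        preexisting[Level.ASSEMBLY] = (str(doc["known_assembly_accession"]),)

    known_top = {"study", "samples", "read_sets", "assembly", "bins", "mags", "aux",
                 "known_sample_accessions", "known_run_accessions",
                 "known_assembly_accession"}
    extras = {k: v for k, v in doc.items() if k not in known_top}
    return SubmissionConfig(str(study), samples, read_sets, assembly, bins, mags,
                            aux, preexisting, extras)


def load_config(path: str | Path) -> SubmissionConfig:
    """Parse a configuration file, resolving relative file paths against it.

    Configuration documents keep paths relative to their own location so a
    dataset directory is relocatable; everything downstream works on the
    absolute paths this returns.
    """
    path = Path(path)
    config = parse_config(path.read_text())
    base = path.parent

    def absolute(p: str) -> str:
        return str(base / p) if not Path(p).is_absolute() else p

    for r in config.read_sets:
        r.files = [absolute(f) for f in r.files]
    if config.assembly is not None:
        config.assembly.fasta_path = absolute(config.assembly.fasta_path)
    for b in config.all_genomes():
        b.fasta_path = absolute(b.fasta_path)
    if config.aux.quality_table:
        config.aux.quality_table = absolute(config.aux.quality_table)
    if config.aux.taxonomy_table:
        config.aux.taxonomy_table = absolute(config.aux.taxonomy_table)
    config.aux.alignment_maps = [absolute(p) for p in config.aux.alignment_maps]
    return config


# ---------------------------------------------------------------------------
# validation


def _fastq_signature_ok(path: Path) -> bool:
    try:
        with open(path) as fh:
            lines = [fh.readline().rstrip("\n") for _ in range(4)]
    except (OSError, UnicodeDecodeError):
        return False
    return (len(lines) == 4 and lines[0].startswith("@") and bool(lines[1])
            and lines[2].startswith("+") and len(lines[3]) == len(lines[1]))


def _fasta_signature_ok(path: Path) -> bool:
    try:
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    return line.startswith(">")
    except (OSError, UnicodeDecodeError):
        return False
    return False


def _alignment_signature_ok(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            head = fh.read(4)
    except OSError:
        return False
    if head[:2] == b"\x1f\x8b":  # BGZF/gzip container (BAM)
        return True
    try:
        with open(path) as fh:
            first = fh.readline()
    except (OSError, UnicodeDecodeError):
        return False
    return first.startswith("@") or first.count("\t") >= 10


def _check_file(report, locus: str, path_str: str, kind: str) -> None:
    path = Path(path_str)
    if not path.is_file():
        report.issues.append(ValidationIssue("ERROR", locus, f"file not found: {path}"))
        return
    if path.stat().st_size == 0:
        report.issues.append(ValidationIssue("ERROR", locus, f"file is empty: {path}"))
        return
    ok = {"fastq": _fastq_signature_ok, "fasta": _fasta_signature_ok,
          "alignment": _alignment_signature_ok}[kind](path)
    if not ok:
        report.issues.append(ValidationIssue(
            "ERROR", locus, f"{path} does not look like a {kind.upper()} file"))


def _check_nonempty(report, locus: str, value) -> bool:
    if value is None or str(value).strip() == "":
        report.issues.append(ValidationIssue("ERROR", locus, "field is empty"))
        return False
    return True


def validate_config(config: SubmissionConfig,
                    scenario: SubmissionScenario) -> ValidationReport:
    """Check the configuration and every referenced file; never raises.

    All problems are collected into one report: errors block submission,
    warnings (e.g. a MAG below the MIMAG high-quality bar) do not.  The check
    is pure — nothing is mutated and no network is touched.
    """
    report = ValidationReport()
    issues = report.issues

    if not matches_accession(config.study_ref, ObjectKind.STUDY):
        issues.append(ValidationIssue(
            "ERROR", "study", f"{config.study_ref!r} is not a study accession"))

    required_sections = {
        Level.SAMPLES: ("samples", config.samples),
        Level.READS: ("read_sets", config.read_sets),
        Level.ASSEMBLY: ("assembly", config.assembly),
        Level.BINS: ("bins", config.bins),
        Level.MAGS: ("mags", config.mags),
    }
    for level in scenario.levels:
        name, value = required_sections[level]
        if not value:
            issues.append(ValidationIssue(
                "ERROR", name, f"scenario includes {level.value} but section is empty"))

    seen_paths: dict[str, str] = {}

    def check_unique_path(locus, path):
        if path in seen_paths:
            issues.append(ValidationIssue(
                "ERROR", locus, f"file path {path!r} already used at {seen_paths[path]}"))
        else:
            seen_paths[path] = locus

    aliases_seen: dict[str, str] = {}

    def check_unique_alias(locus, alias):
        if alias in aliases_seen:
            issues.append(ValidationIssue(
                "ERROR", locus, f"duplicate alias {alias!r} (also at {aliases_seen[alias]})"))
        else:
            aliases_seen[alias] = locus

    known_samples = config.sample_aliases() | set(
        config.preexisting.get(Level.SAMPLES, ()) or scenario.preexisting.get(Level.SAMPLES, ()))
    known_runs = config.read_aliases() | set(
        config.preexisting.get(Level.READS, ()) or scenario.preexisting.get(Level.READS, ()))

    def check_ref(locus, ref, pool: set, kind: ObjectKind):
        if ref not in pool and not matches_accession(ref, kind):
            issues.append(ValidationIssue(
                "ERROR", locus,
                f"{ref!r} is neither a declared alias nor a {kind.value} accession"))

    for i, s in enumerate(config.samples):
        path = f"samples.{i}"
        check_unique_alias(f"{path}.alias", s.alias)
        for key in ("title", "scientific_name"):
            _check_nonempty(report, f"{path}.{key}", getattr(s, key))
        for key in ("collection_date", "location"):
            value = getattr(s, key)
            if not _check_nonempty(report, f"{path}.{key}", value):
                continue
            if key == "collection_date" and value != MISSING_KEYWORD \
                    and not _ISO_DATE.match(value):
                issues.append(ValidationIssue(
                    "WARNING", f"{path}.{key}",
                    f"{value!r} is not an ISO-8601 date or the 'missing' keyword"))

    for i, r in enumerate(config.read_sets):
        path = f"read_sets.{i}"
        check_unique_alias(f"{path}.alias", r.alias)
        for key in ("platform", "instrument", "library_source",
                    "library_selection", "library_strategy"):
            _check_nonempty(report, f"{path}.{key}", getattr(r, key))
        check_ref(f"{path}.sample_ref", r.sample_ref, known_samples, ObjectKind.SAMPLE)
        if r.library_layout not in ("SINGLE", "PAIRED"):
            issues.append(ValidationIssue(
                "ERROR", f"{path}.library_layout",
                f"{r.library_layout!r} is neither SINGLE nor PAIRED"))
        expected = 2 if r.library_layout == "PAIRED" else 1
        if len(r.files) != expected:
            issues.append(ValidationIssue(
                "ERROR", f"{path}.files",
                f"{r.library_layout} layout requires exactly {expected} file(s), "
                f"got {len(r.files)}"))
        for f in r.files:
            check_unique_path(f"{path}.files", f)
            _check_file(report, f"{path}.files", f, "fastq")
        if r.checksums is not None:
            if len(r.checksums) != len(r.files):
                issues.append(ValidationIssue(
                    "ERROR", f"{path}.checksums", "one checksum per file required"))
            for c in r.checksums:
                if not _MD5_HEX.match(c):
                    issues.append(ValidationIssue(
                        "ERROR", f"{path}.checksums",
                        f"{c!r} is not a 32-digit hex MD5"))

    if config.assembly is not None:
        a, path = config.assembly, "assembly"
        for key in ("name", "program", "molecule_type"):
            _check_nonempty(report, f"{path}.{key}", getattr(a, key))
        for ref in a.sample_refs:
            check_ref(f"{path}.sample_refs", ref, known_samples, ObjectKind.SAMPLE)
        for ref in a.run_refs:
            check_ref(f"{path}.run_refs", ref, known_runs, ObjectKind.RUN)
        check_unique_path(f"{path}.fasta_path", a.fasta_path)
        _check_file(report, f"{path}.fasta_path", a.fasta_path, "fasta")

    quality: dict[str, QualityStats] = {}
    need_quality = bool(config.bins or config.mags) and (
        Level.BINS in scenario.levels or Level.MAGS in scenario.levels)
    if need_quality:
        for key in ("quality_table", "taxonomy_table"):
            value = getattr(config.aux, key)
            if not value:
                issues.append(ValidationIssue(
                    "ERROR", f"aux.{key}", "required when submitting bins/MAGs"))
            elif not Path(value).is_file():
                issues.append(ValidationIssue(
                    "ERROR", f"aux.{key}", f"file not found: {value}"))
        if config.aux.quality_table and Path(config.aux.quality_table).is_file():
            try:
                quality = read_quality_table(config.aux.quality_table)
            except Exception as exc:
                issues.append(ValidationIssue("ERROR", "aux.quality_table", str(exc)))

    for kind, records in (("bins", config.bins), ("mags", config.mags)):
        for i, b in enumerate(records):
            path = f"{kind}.{i}"
            check_unique_alias(f"{path}.bin_id", b.bin_id)
            _check_nonempty(report, f"{path}.binning_software", b.binning_software)
            check_unique_path(f"{path}.fasta_path", b.fasta_path)
            _check_file(report, f"{path}.fasta_path", b.fasta_path, "fasta")
            if need_quality and quality and b.bin_id not in quality:
                issues.append(ValidationIssue(
                    "ERROR", f"{path}.bin_id",
                    f"{b.bin_id!r} absent from the quality table"))
            if kind == "mags" and b.bin_id in quality:
                tier = classify_mimag(quality[b.bin_id])
                if tier is not MimagTier.HIGH:
                    issues.append(ValidationIssue(
                        "WARNING", f"{path}.bin_id",
                        f"MAG quality is MIMAG {tier.value} "
                        f"(completeness {quality[b.bin_id].completeness}, "
                        f"contamination {quality[b.bin_id].contamination}); "
                        "the MIMAG high-quality bar is completeness > 90 and "
                        "contamination < 5"))
            if isinstance(b, MagRecord) and b.derived_bin_id is not None \
                    and b.derived_bin_id not in config.bin_ids():
                issues.append(ValidationIssue(
                    "ERROR", f"{path}.derived_bin_id",
                    f"{b.derived_bin_id!r} is not a declared bin"))

    needs_inference = (
        (config.assembly is not None and config.assembly.coverage is None
         and Level.ASSEMBLY in scenario.levels)
        or any(b.coverage is None for b in config.all_genomes()))
    if needs_inference and (Level.ASSEMBLY in scenario.levels
                            or Level.BINS in scenario.levels
                            or Level.MAGS in scenario.levels):
        if not config.aux.alignment_maps:
            issues.append(ValidationIssue(
                "ERROR", "aux.alignment_map",
                "coverage must be inferred but no alignment map is configured"))
        for p in config.aux.alignment_maps:
            _check_file(report, "aux.alignment_map", p, "alignment")

    return report
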