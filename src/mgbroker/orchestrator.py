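"""Plan and execute a dependency-ordered submission with accession tracking.

The execution order mirrors the dependency structure of a metagenomics
deposition: samples first (their accessions anchor everything else), then
sequencing runs, then the assembly — preceded by a virtual sample object when
it is a co-assembly — then, per bin and per MAG, a virtual sample
registration followed by the genome upload.  Every receipt is parsed and its
accessions enter the ledger before any dependent step runs; the first failed
receipt aborts the run with a report of what was completed.

Unresolvable bin/MAG taxonomies refuse the run outright, before any service
interaction.  A dry run performs planning, coverage inference, document
generation and staging, but makes no service call and assigns no accession.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .config import SubmissionConfig, ValidationReport, validate_config
from .documents import (
    StagedItem,
    build_manifest,
    build_sample_set,
    build_virtual_sample,
    parse_receipt,
    stage_item,
    virtual_sample_alias,
    wrap_sample_set,
)
from .errors import (
    PreconditionError,
    ProductionOptInError,
    TaxonomyHaltError,
    TransportError,
)
from .model import (
    AccessionLedger,
    AssemblyRecord,
    BinRecord,
    Level,
    MagRecord,
    ObjectKind,
    Receipt,
    SubmissionScenario,
    TaxonomyAssignment,
    matches_accession,
)
from .readers import (
    CoverageStats,
    compute_coverage,
    fasta_contig_names,
    read_quality_table,
    read_taxonomy_table,
)
from .taxonomy import (
    FixtureTaxonomyClient,
    ResolutionFailure,
    TaxonomyQueryClient,
    resolve_all,
)

log = logging.getLogger("mgbroker")

# Taxon used for a co-assembly's virtual sample when the constituent samples
# are preexisting accessions whose metadata is not in the configuration.
_GENERIC_METAGENOME = TaxonomyAssignment("metagenome", 256318, source="RESOLVED")

_LEVEL_KIND = {Level.SAMPLES: ObjectKind.SAMPLE, Level.READS: ObjectKind.RUN,
               Level.ASSEMBLY: ObjectKind.ANALYSIS}


class StepKind(str, Enum):
    REGISTER_SAMPLES = "REGISTER_SAMPLES"
    UPLOAD_READS = "UPLOAD_READS"
    REGISTER_VIRTUAL_SAMPLE = "REGISTER_VIRTUAL_SAMPLE"
    UPLOAD_ASSEMBLY = "UPLOAD_ASSEMBLY"
    UPLOAD_BIN = "UPLOAD_BIN"
    UPLOAD_MAG = "UPLOAD_MAG"


@dataclass(frozen=True)
class Step:
    kind: StepKind
    payload: str               # record alias / bin id / assembly name
    depends: tuple[str, ...]   # aliases or accession literals required first

    def produces(self, plan: "SubmissionPlan") -> tuple[str, ...]:
        if self.kind is StepKind.REGISTER_SAMPLES:
            return tuple(s.alias for s in plan.config.samples)
        return (self.payload,)


@dataclass
class SubmissionPlan:
    scenario: SubmissionScenario
    config: SubmissionConfig
    steps: list[Step]
    preseed: list[tuple[str, ObjectKind]] = field(default_factory=list)

    def validate_topology(self) -> None:
        """Every dependency must be produced earlier, preseeded, or an accession."""
        available = {acc for acc, _ in self.preseed}
        for i, step in enumerate(self.steps):
            for dep in step.depends:
                if dep not in available and not matches_accession(dep):
                    raise PreconditionError(
                        f"step {i} ({step.kind.value} {step.payload}): "
                        f"dependency {dep!r} not satisfied by any earlier step")
            available.update(step.produces(self))


def _bin_origin_refs(config: SubmissionConfig,
                     scenario: SubmissionScenario) -> tuple[str, ...]:
    if config.assembly is not None:
        return tuple(config.assembly.sample_refs)
    pre = (config.preexisting.get(Level.SAMPLES)
           or scenario.preexisting.get(Level.SAMPLES))
    if pre:
        return tuple(pre)
    return tuple(s.alias for s in config.samples)


def plan_submission(scenario: SubmissionScenario, config: SubmissionConfig,
                    validation: ValidationReport) -> SubmissionPlan:
    """Derive the ordered step list for a validated configuration.

    Levels covered by preexisting accessions contribute no steps but seed the
    ledger so downstream references resolve.
    """
    if validation is None or not validation.ok:
        raise PreconditionError(
            "configuration must be validated with zero errors before planning")
    scenario.validate()
    for level in scenario.levels:
        section = {Level.SAMPLES: config.samples, Level.READS: config.read_sets,
                   Level.ASSEMBLY: config.assembly, Level.BINS: config.bins,
                   Level.MAGS: config.mags}[level]
        if not section:
            raise PreconditionError(
                f"scenario requests {level.value} but the configuration has none")

    preseed: list[tuple[str, ObjectKind]] = []
    merged_pre = dict(scenario.preexisting)
    merged_pre.update(config.preexisting)
    for level, accessions in merged_pre.items():
        if level in scenario.levels:
            continue
        kind = _LEVEL_KIND.get(level, ObjectKind.ANALYSIS)
        preseed += [(acc, kind) for acc in accessions]

    steps: list[Step] = []
    if Level.SAMPLES in scenario.levels:
        steps.append(Step(StepKind.REGISTER_SAMPLES, "samples", ()))
    if Level.READS in scenario.levels:
        steps += [Step(StepKind.UPLOAD_READS, rs.alias, (rs.sample_ref,))
                  for rs in config.read_sets]
    asm_sample_ref: str | None = None
    if Level.ASSEMBLY in scenario.levels:
        asm = config.assembly
        if asm.is_coassembly:
            asm_sample_ref = virtual_sample_alias(asm)
            steps.append(Step(StepKind.REGISTER_VIRTUAL_SAMPLE, asm_sample_ref,
                              tuple(asm.sample_refs)))
        else:
            asm_sample_ref = asm.sample_refs[0]
        steps.append(Step(StepKind.UPLOAD_ASSEMBLY, asm.name,
                          (asm_sample_ref, *asm.run_refs)))
    origin = _bin_origin_refs(config, scenario)
    for level, records, upload_kind in (
            (Level.BINS, config.bins, StepKind.UPLOAD_BIN),
            (Level.MAGS, config.mags, StepKind.UPLOAD_MAG)):
        if level not in scenario.levels:
            continue
        for b in records:
            vs_alias = virtual_sample_alias(b)
            steps.append(Step(StepKind.REGISTER_VIRTUAL_SAMPLE, vs_alias, origin))
            steps.append(Step(upload_kind, b.bin_id, (vs_alias,)))
    plan = SubmissionPlan(scenario, config, steps, preseed)
    plan.validate_topology()
    return plan


@dataclass
class ServiceEndpoints:
    """Where documents, taxonomy queries and uploads go.

    DEVELOPMENT is the default mode; PRODUCTION must be confirmed explicitly
    or execution refuses to start.  The uploader is a pluggable contract
    taking a staged item and returning a receipt, so the mock broker and an
    external upload tool are interchangeable.
    """

    register: Callable[[str], str]
    taxonomy: TaxonomyQueryClient
    upload: Callable[[StagedItem], Receipt]
    mode: str = "DEVELOPMENT"
    production_confirmed: bool = False
    retries: int = 3
    retry_wait: float = 0.5

    def check_mode(self) -> None:
        if self.mode == "PRODUCTION" and not self.production_confirmed:
            raise ProductionOptInError(
                "PRODUCTION mode requires the explicit confirmation flag")


@dataclass
class RunReport:
    total_steps: int
    completed: list[Step] = field(default_factory=list)
    aborted_at: int | None = None
    messages: list[tuple[str, str]] = field(default_factory=list)
    dry_run: bool = False

    @property
    def success(self) -> bool:
        return self.aborted_at is None


def infer_coverage(config: SubmissionConfig,
                   scenario: SubmissionScenario) -> dict[str, CoverageStats | float]:
    """Fill in coverage wherever the configuration left it unset.

    Assembly coverage uses the whole alignment map; per-bin/MAG coverage uses
    the same map restricted to the contigs of the genome's FASTA.  Explicit
    configuration values are kept as-is.
    """
    out: dict[str, CoverageStats | float] = {}
    need_asm = (Level.ASSEMBLY in scenario.levels and config.assembly is not None)
    genomes = []
    if Level.BINS in scenario.levels:
        genomes += config.bins
    if Level.MAGS in scenario.levels:
        genomes += config.mags
    alignment = config.aux.alignment_maps[0] if config.aux.alignment_maps else None
    if need_asm:
        key = f"assembly:{config.assembly.name}"
        if config.assembly.coverage is not None:
            out[key] = config.assembly.coverage
        else:
            out[key] = compute_coverage(alignment)
    for b in genomes:
        if b.coverage is not None:
            out[b.bin_id] = b.coverage
        else:
            out[b.bin_id] = compute_coverage(
                alignment, restrict_to=set(fasta_contig_names(b.fasta_path)))
    return out


def _call_with_retry(fn: Callable, endpoints: ServiceEndpoints, what: str):
    for attempt in range(endpoints.retries + 1):
        try:
            return fn()
        except TransportError:
            if attempt == endpoints.retries:
                raise
            wait = endpoints.retry_wait * (2 ** attempt)
            log.warning("transport failure during %s; retrying in %.1fs", what, wait)
            time.sleep(wait)


def _derived_platform(config: SubmissionConfig) -> str:
    if config.assembly is not None and config.assembly.platform:
        return config.assembly.platform
    platforms = sorted({rs.platform for rs in config.read_sets if rs.platform})
    return ",".join(platforms) if platforms else "UNKNOWN"


def execute_plan(
    plan: SubmissionPlan,
    endpoints: ServiceEndpoints,
    assignments: Mapping[str, TaxonomyAssignment],
    workdir: str | Path,
    failures: Sequence[ResolutionFailure] = (),
    dry_run: bool = False,
) -> tuple[AccessionLedger, RunReport]:
    """Run the plan in order, threading accessions through the ledger.

    Refuses to start while any taxonomy failure is outstanding.  Transport
    errors are retried with backoff; a rejected receipt is never retried and
    aborts the run.  In a dry run the ledger stays empty and placeholder
    accessions back the generated documents.
    """
    if failures:
        raise TaxonomyHaltError(failures)
    endpoints.check_mode()
    config, scenario = plan.config, plan.scenario
    workdir = Path(workdir)
    report = RunReport(total_steps=len(plan.steps), dry_run=dry_run)

    ledger = AccessionLedger()
    for accession, kind in plan.preseed:
        ledger.add(accession, kind, accession)
    # dry runs build documents against placeholder accessions and return an
    # empty ledger; real runs use the one and only ledger throughout
    working = AccessionLedger()
    placeholder_counter = [0]
    for accession, kind in plan.preseed:
        working.add(accession, kind, accession)

    def placeholder(kind: ObjectKind) -> str:
        placeholder_counter[0] += 1
        prefix = {ObjectKind.SAMPLE: "ERS", ObjectKind.RUN: "ERR",
                  ObjectKind.ANALYSIS: "ERZ"}[kind]
        return f"{prefix}{900000 + placeholder_counter[0]:07d}"

    coverage = infer_coverage(config, scenario)
    platform = _derived_platform(config)
    docs_dir = workdir / "documents"
    docs_dir.mkdir(parents=True, exist_ok=True)

    samples_by_alias = {s.alias: s for s in config.samples}
    reads_by_alias = {rs.alias: rs for rs in config.read_sets}
    genomes_by_id = {b.bin_id: b for b in config.all_genomes()}

    def record_receipt(step_index: int, receipt: Receipt) -> bool:
        if not receipt.success:
            report.aborted_at = step_index
            report.messages += receipt.messages
            return False
        for a in receipt.assignments:
            if not dry_run:
                ledger.add(a.alias, a.kind, a.accession, step_index=step_index)
            working.add(a.alias, a.kind, a.accession, step_index=step_index)
        return True

    def register_document(step_index: int, alias: str, xml: str,
                          produced: list[tuple[str, ObjectKind]]) -> bool:
        (docs_dir / f"{alias}.xml").write_text(xml, encoding="utf-8")
        if dry_run:
            for name, kind in produced:
                working.add(name, kind, placeholder(kind), step_index=step_index)
            return True
        receipt_xml = _call_with_retry(lambda: endpoints.register(xml), endpoints,
                                       f"step {step_index}")
        return record_receipt(step_index, parse_receipt(receipt_xml))

    def upload_staged(step_index: int, staged: StagedItem, alias: str,
                      kind: ObjectKind) -> bool:
        if dry_run:
            working.add(alias, kind, placeholder(kind), step_index=step_index)
            return True
        receipt = _call_with_retry(lambda: endpoints.upload(staged), endpoints,
                                   f"step {step_index}")
        return record_receipt(step_index, receipt)

    def virtual_sample_assignment(step: Step) -> TaxonomyAssignment:
        if config.assembly is not None \
                and step.payload == virtual_sample_alias(config.assembly):
            first = config.assembly.sample_refs[0]
            if first in samples_by_alias:
                s = samples_by_alias[first]
                return TaxonomyAssignment(s.scientific_name, s.taxid,
                                          source="RESOLVED")
            return _GENERIC_METAGENOME
        bin_id = step.payload.removesuffix("_virtual_sample")
        if bin_id not in assignments:
            raise PreconditionError(
                f"no taxonomy assignment for {bin_id!r}; resolution incomplete")
        return assignments[bin_id]

    for i, step in enumerate(plan.steps):
        log.info("step %d/%d: %s %s [%s]", i + 1, len(plan.steps),
                 step.kind.value, step.payload, endpoints.mode)
        ok = True
        if step.kind is StepKind.REGISTER_SAMPLES:
            xml = build_sample_set(config.samples)
            ok = register_document(
                i, "samples", xml,
                [(s.alias, ObjectKind.SAMPLE) for s in config.samples])
        elif step.kind is StepKind.REGISTER_VIRTUAL_SAMPLE:
            assignment = virtual_sample_assignment(step)
            if config.assembly is not None \
                    and step.payload == virtual_sample_alias(config.assembly):
                item: AssemblyRecord | BinRecord = config.assembly
                origin: tuple[str, ...] = tuple(config.assembly.sample_refs)
            else:
                item = genomes_by_id[step.payload.removesuffix("_virtual_sample")]
                origin = _bin_origin_refs(config, scenario)
            element = build_virtual_sample(item, assignment, working,
                                           origin_refs=origin)
            ok = register_document(i, step.payload, wrap_sample_set([element]),
                                   [(step.payload, ObjectKind.SAMPLE)])
        elif step.kind is StepKind.UPLOAD_READS:
            rs = reads_by_alias[step.payload]
            manifest = build_manifest(Level.READS, rs, working, config.study_ref)
            staged = stage_item(rs, manifest, workdir, Level.READS, rs.alias)
            ok = upload_staged(i, staged, rs.alias, ObjectKind.RUN)
        elif step.kind is StepKind.UPLOAD_ASSEMBLY:
            asm = config.assembly
            manifest = build_manifest(
                Level.ASSEMBLY, asm, working, config.study_ref,
                sample_ref=step.depends[0],
                coverage=coverage[f"assembly:{asm.name}"],
                run_refs=asm.run_refs, platform=platform)
            staged = stage_item(asm, manifest, workdir, Level.ASSEMBLY, asm.name)
            ok = upload_staged(i, staged, asm.name, ObjectKind.ANALYSIS)
        else:  # UPLOAD_BIN / UPLOAD_MAG
            b = genomes_by_id[step.payload]
            level = Level.MAGS if step.kind is StepKind.UPLOAD_MAG else Level.BINS
            program = (config.assembly.program if config.assembly is not None
                       else b.binning_software)
            molecule = (config.assembly.molecule_type
                        if config.assembly is not None else "genomic DNA")
            manifest = build_manifest(
                level, b, working, config.study_ref,
                sample_ref=virtual_sample_alias(b),
                coverage=coverage[b.bin_id], platform=platform,
                program=program, molecule_type=molecule)
            staged = stage_item(b, manifest, workdir, level, b.bin_id)
            ok = upload_staged(i, staged, b.bin_id, ObjectKind.ANALYSIS)
        if not ok:
            log.error("step %d failed; aborting run", i + 1)
            break
        report.completed.append(step)

    return (ledger if not dry_run else AccessionLedger()), report


def write_summary(ledger: AccessionLedger, path: str | Path) -> Path:
    """Tab-separated accession summary: alias, object kind, accession, step."""
    path = Path(path)
    lines = ["alias\tkind\taccession\tstep_index"]
    lines += [f"{alias}\t{e.kind.value}\t{e.accession}\t{e.step_index}"
              for alias, e in ledger.items()]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="")
    return path


@dataclass
class SubmissionOutcome:
    validation: ValidationReport
    assignments: dict[str, TaxonomyAssignment] = field(default_factory=dict)
    failures: list[ResolutionFailure] = field(default_factory=list)
    ledger: AccessionLedger | None = None
    run: RunReport | None = None

    @property
    def success(self) -> bool:
        return (self.validation.ok and not self.failures
                and self.run is not None and self.run.success)


def attach_genome_metadata(config: SubmissionConfig) -> None:
    """Fill bin/MAG quality and lineage from the configured auxiliary tables.

    Values already present on a record (or a taxonomy override) are kept.
    """
    quality = (read_quality_table(config.aux.quality_table)
               if config.aux.quality_table else {})
    lineages = (read_taxonomy_table(config.aux.taxonomy_table)
                if config.aux.taxonomy_table else {})
    for b in config.all_genomes():
        if b.quality is None and b.bin_id in quality:
            b.quality = quality[b.bin_id]
        if b.lineage is None and b.bin_id in lineages:
            b.lineage = lineages[b.bin_id]


def submit(config: SubmissionConfig, scenario: SubmissionScenario,
           endpoints: ServiceEndpoints, workdir: str | Path,
           dry_run: bool = False) -> SubmissionOutcome:
    """Validate, resolve taxonomy, plan and execute in one call.

    Stops after validation if any error is reported, and after taxonomy
    resolution if any bin/MAG is unresolvable — in both cases without a
    single service interaction.
    """
    endpoints.check_mode()
    validation = validate_config(config, scenario)
    outcome = SubmissionOutcome(validation)
    if not validation.ok:
        return outcome
    attach_genome_metadata(config)
    genomes = []
    if Level.BINS in scenario.levels:
        genomes += config.bins
    if Level.MAGS in scenario.levels:
        genomes += config.mags
    client = FixtureTaxonomyClient() if dry_run else endpoints.taxonomy
    outcome.assignments, outcome.failures = resolve_all(genomes, client)
    if outcome.failures:
        return outcome
    plan = plan_submission(scenario, config, validation)
    outcome.ledger, outcome.run = execute_plan(
        plan, endpoints, outcome.assignments, workdir,
        failures=outcome.failures, dry_run=dry_run)
    return outcome
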