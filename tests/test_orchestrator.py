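"""Planning, dependency-ordered execution, halting, summaries."""

import itertools

import pytest
import yaml

from mgbroker.config import load_config, parse_config, validate_config
from mgbroker.documents import Manifest
from mgbroker.errors import (
    PreconditionError,
    ProductionOptInError,
    TaxonomyHaltError,
    TransportError,
)
from mgbroker.model import AccessionLedger, Level, ObjectKind, Receipt
from mgbroker.orchestrator import (
    ServiceEndpoints,
    StepKind,
    execute_plan,
    plan_submission,
    submit,
    write_summary,
)
from mgbroker.taxonomy import ResolutionFailure
from .conftest import FULL_LEVELS, scenario, scenario_config_doc


def validated(config, scn):
    report = validate_config(config, scn)
    assert report.ok, [str(i) for i in report.errors]
    return report


class TestPlanning:
    def test_step_count_for_typical_study(self, toy_config):
        """2 samples + 2 read sets + co-assembly + 3 bins: 1+2+1+1+6 = 11 steps."""
        scn = scenario(*FULL_LEVELS)
        plan = plan_submission(scn, toy_config, validated(toy_config, scn))
        assert len(plan.steps) == 11
        kinds = [s.kind for s in plan.steps]
        assert kinds == [
            StepKind.REGISTER_SAMPLES,
            StepKind.UPLOAD_READS, StepKind.UPLOAD_READS,
            StepKind.REGISTER_VIRTUAL_SAMPLE,   # co-assembly virtual sample
            StepKind.UPLOAD_ASSEMBLY,
            StepKind.REGISTER_VIRTUAL_SAMPLE, StepKind.UPLOAD_BIN,
            StepKind.REGISTER_VIRTUAL_SAMPLE, StepKind.UPLOAD_BIN,
            StepKind.REGISTER_VIRTUAL_SAMPLE, StepKind.UPLOAD_BIN,
        ]

    def test_preexisting_levels_seed_ledger_without_steps(self, toy):
        scn = scenario(Level.BINS, preexisting={
            Level.SAMPLES: ("ERS9000001", "ERS9000002"),
            Level.ASSEMBLY: ("ERZ9000001",)})
        doc = scenario_config_doc(toy, {Level.BINS}, scn.preexisting)
        config = parse_config(yaml.safe_dump(doc, sort_keys=False))
        config.aux.quality_table = str(toy.root / "quality.tsv")
        config.aux.taxonomy_table = str(toy.root / "classification.tsv")
        config.aux.alignment_maps = [str(toy.root / "alignment.sam")]
        for b in config.bins:
            b.fasta_path = str(toy.root / b.fasta_path)
        plan = plan_submission(scn, config, validated(config, scn))
        assert all(s.kind in (StepKind.REGISTER_VIRTUAL_SAMPLE, StepKind.UPLOAD_BIN)
                   for s in plan.steps)
        assert len(plan.steps) == 6
        assert ("ERS9000001", ObjectKind.SAMPLE) in plan.preseed

    def test_unvalidated_config_refused(self, toy_config):
        with pytest.raises(PreconditionError):
            plan_submission(scenario(*FULL_LEVELS), toy_config, None)

    def test_empty_section_for_requested_level(self, toy_config):
        toy_config.mags = []
        scn = scenario(*FULL_LEVELS, Level.MAGS)
        with pytest.raises(PreconditionError, match="MAGS"):
            plan_submission(scn, toy_config, validated(toy_config,
                                                       scenario(*FULL_LEVELS)))

    def test_topology_holds_for_level_combinations(self, toy):
        """Every planned step's dependencies are met by earlier steps."""
        config = load_config(toy.config_path)
        combos = [{Level.SAMPLES}, {Level.SAMPLES, Level.READS},
                  {Level.SAMPLES, Level.READS, Level.ASSEMBLY}, FULL_LEVELS]
        for levels in combos:
            scn = scenario(*levels)
            plan = plan_submission(scn, config, validated(config, scn))
            plan.validate_topology()  # raises on violation

    def test_shuffled_plan_fails_topology(self, toy_config):
        scn = scenario(*FULL_LEVELS)
        plan = plan_submission(scn, toy_config, validated(toy_config, scn))
        plan.steps.reverse()
        with pytest.raises(PreconditionError):
            plan.validate_topology()


def run_toy(toy, endpoints, workdir, dry_run=False, levels=FULL_LEVELS):
    config = load_config(toy.config_path)
    return submit(config, scenario(*levels), endpoints, workdir, dry_run=dry_run)


class TestExecution:
    def test_one_accession_per_object(self, toy, mock_endpoints, tmp_path):
        _, endpoints = mock_endpoints()
        outcome = run_toy(toy, endpoints, tmp_path / "work")
        assert outcome.success
        # 2 samples + 2 runs + 1 co-assembly virtual sample + 1 assembly
        # + 3 bin virtual samples + 3 bin analyses
        assert len(outcome.ledger) == 12

    def test_reruns_are_byte_identical(self, toy, mock_endpoints, tmp_path):
        summaries, manifests = [], []
        for run in ("a", "b"):
            _, endpoints = mock_endpoints()
            outcome = run_toy(toy, endpoints, tmp_path / run)
            path = write_summary(outcome.ledger, tmp_path / f"{run}.tsv")
            summaries.append(path.read_bytes())
            manifests.append(sorted(
                p.read_bytes() for p in (tmp_path / run).rglob("manifest.tsv")))
        assert summaries[0] == summaries[1]
        assert manifests[0] == manifests[1]

    def test_taxonomy_failure_halts_before_any_service_call(
            self, toy_config, mock_endpoints, tmp_path):
        registry, endpoints = mock_endpoints()
        scn = scenario(*FULL_LEVELS)
        plan = plan_submission(scn, toy_config, validated(toy_config, scn))
        failure = ResolutionFailure("bin_3", ["uncultured Imaginariaceae bacterium"],
                                    "no match")
        with pytest.raises(TaxonomyHaltError, match="bin_3"):
            execute_plan(plan, endpoints, {}, tmp_path / "work",
                         failures=[failure])
        assert registry.register_calls == 0
        assert endpoints.upload.upload_calls == 0

    def test_dry_run_stages_but_never_calls(self, toy, mock_endpoints, tmp_path):
        registry, endpoints = mock_endpoints()
        outcome = run_toy(toy, endpoints, tmp_path / "work", dry_run=True)
        assert registry.register_calls == 0
        assert endpoints.upload.upload_calls == 0
        assert len(outcome.ledger) == 0
        staged = list((tmp_path / "work").rglob("manifest.tsv"))
        assert len(staged) == 6  # 2 read sets + assembly + 3 bins
        docs = list((tmp_path / "work" / "documents").glob("*.xml"))
        assert len(docs) == 5   # samples + co-assembly vs + 3 bin vs

    def test_abort_keeps_earlier_accessions(self, toy, mock_endpoints, tmp_path):
        registry, endpoints = mock_endpoints()
        real_upload = endpoints.upload
        calls = {"n": 0}

        def flaky_upload(staged):
            calls["n"] += 1
            if calls["n"] == 3:  # fail on the assembly upload
                return Receipt(False, [], [("ERROR", "rejected by broker")])
            return real_upload(staged)

        endpoints.upload = flaky_upload
        outcome = run_toy(toy, endpoints, tmp_path / "work")
        assert not outcome.success
        assert outcome.run.aborted_at == 4
        # samples, 2 runs and the co-assembly virtual sample made it
        assert len(outcome.ledger) == 5
        summary = write_summary(outcome.ledger, tmp_path / "s.tsv").read_text()
        assert summary.count("\n") == 6  # header + 5 rows
        assert "rejected by broker" in outcome.run.messages[0][1]

    def test_transport_failures_retried(self, toy, mock_endpoints, tmp_path):
        registry, endpoints = mock_endpoints()
        attempts = {"n": 0}
        real_register = endpoints.register

        def flaky_register(xml):
            attempts["n"] += 1
            if attempts["n"] <= 2:
                raise TransportError("connection reset")
            return real_register(xml)

        endpoints.register = flaky_register
        outcome = run_toy(toy, endpoints, tmp_path / "work")
        assert outcome.success and attempts["n"] > 2

    def test_production_requires_opt_in(self, toy, mock_endpoints, tmp_path):
        _, endpoints = mock_endpoints()
        endpoints.mode = "PRODUCTION"
        with pytest.raises(ProductionOptInError):
            run_toy(toy, endpoints, tmp_path / "work")
        endpoints.production_confirmed = True
        assert run_toy(toy, endpoints, tmp_path / "work").success

    def test_validation_errors_block_without_service_calls(
            self, toy, mock_endpoints, tmp_path):
        registry, endpoints = mock_endpoints()
        config = load_config(toy.config_path)
        config.assembly.fasta_path = str(toy.root / "ghost.fasta")
        outcome = submit(config, scenario(*FULL_LEVELS), endpoints,
                         tmp_path / "work")
        assert not outcome.validation.ok and outcome.ledger is None
        assert registry.register_calls == 0

    def test_mags_get_fresh_virtual_samples(self, tmp_path, mock_endpoints):
        from mgbroker.mock import generate_toy_dataset
        ds = generate_toy_dataset(tmp_path / "ds", seed=11, n_mags=2)
        _, endpoints = mock_endpoints()
        outcome = run_toy(ds, endpoints, tmp_path / "work",
                          levels=FULL_LEVELS | {Level.MAGS})
        assert outcome.success
        # 12 as before + 2 MAG virtual samples + 2 MAG analyses
        assert len(outcome.ledger) == 16
        assert "mag_1_virtual_sample" in outcome.ledger
        assert "bin_1_virtual_sample" in outcome.ledger


class TestSummary:
    def test_row_per_ledger_entry(self, toy, mock_endpoints, tmp_path):
        _, endpoints = mock_endpoints()
        outcome = run_toy(toy, endpoints, tmp_path / "work")
        text = write_summary(outcome.ledger, tmp_path / "s.tsv").read_text()
        lines = text.strip().split("\n")
        assert lines[0] == "alias\tkind\taccession\tstep_index"
        assert len(lines) == 1 + len(outcome.ledger)
        assert lines[1].split("\t") == ["sample_1", "SAMPLE", "ERS0000001", "0"]

    def test_empty_ledger_header_only(self, tmp_path):
        text = write_summary(AccessionLedger(), tmp_path / "s.tsv").read_text()
        assert text == "alias\tkind\taccession\tstep_index\n"


def test_inferred_coverage_lands_in_manifests(toy, mock_endpoints, tmp_path):
    """Unset coverage is inferred from the alignment map: whole-map fold for
    the assembly, bin-contig-restricted fold for each bin."""
    _, endpoints = mock_endpoints()
    outcome = run_toy(toy, endpoints, tmp_path / "work")
    assert outcome.success
    asm_manifest = Manifest.parse(
        (tmp_path / "work" / "assembly" / "toy_coassembly" / "manifest.tsv")
        .read_text())
    expected_asm = toy.total_aligned_bases / sum(toy.contig_lengths.values())
    assert asm_manifest.get("COVERAGE") == f"{expected_asm:.1f}"
    for bin_id, contigs in toy.bin_contigs.items():
        m = Manifest.parse(
            (tmp_path / "work" / "bins" / bin_id / "manifest.tsv").read_text())
        expected = (sum(toy.per_contig_aligned[c] for c in contigs)
                    / sum(toy.contig_lengths[c] for c in contigs))
        assert m.get("COVERAGE") == f"{expected:.1f}"
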