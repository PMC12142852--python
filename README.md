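# mgbroker

Scenario-driven brokering of genome-resolved metagenomics submissions to an
INSDC-style sequence registry (the workflow of the European Nucleotide
Archive).

A complete metagenomics deposition spans many objects — samples, sequencing
runs, a (co-)assembly, binned contigs, and metagenome-assembled genomes
(MAGs) — each with its own metadata dialect (sample XML, tab-separated Webin
manifests), its own mandatory fields, and accessions that later steps must
reference. Doing this by hand for hundreds of bins is slow and error-prone,
and is one reason published studies often lack processed data. `mgbroker`
collapses the whole process into one configuration document and one
dependency-ordered run, for researchers who need to deposit a full study and
for pipeline authors who want submissions as a scripted step.

## What it does

* **Scenario templating** (`makecfg`): from the set of data levels to submit
  — samples, reads, assembly, bins, MAGs — generate a YAML form containing
  only the mandatory fields, each with an explanatory comment and example.
  Extending an already-deposited study swaps metadata sections for
  accession-entry fields.
* **Validation**: every cross-reference, file, and format signature (FASTA,
  FASTQ, SAM/BAM) is checked up front; all problems are reported at once.
  Errors block submission, warnings (e.g. a MAG below the MIMAG high-quality
  bar) do not.
* **Inference**: fold coverage is computed from alignment maps where the
  configuration leaves it unset — assembly-wide for the assembly, restricted
  to a bin's contigs for each bin:
  `fold = aligned reference-consuming bases (CIGAR M/=/X/D) / reference length`.
  MIMAG tiers follow the community bars (high: completeness > 90 %,
  contamination < 5 %; medium: ≥ 50 % and < 10 %).
* **Environmental taxonomy resolution**: classification output (GTDB-Tk
  style) names rank taxa, but uncultivated genomes must be deposited under
  environmental organism-level taxa. From the lowest classified rank the
  resolver derives candidate names — e.g. family *Enterobacteriaceae*
  (taxid 543, not submittable) → `uncultured Enterobacteriaceae bacterium`
  (taxid 218034) — and accepts only exact, submittable registry matches.
  Unresolvable bins halt the run with a list to fix, before any service call.
* **Execution** (`submit`): samples → reads → co-assembly virtual sample →
  assembly → per-bin/MAG virtual sample + upload, with receipts parsed and
  accessions threaded through a write-once ledger, ending in a tab-separated
  accession summary. Development mode is the default; production requires an
  explicit confirmation flag.
* **Offline by construction**: a deterministic mock registry, mock upload
  broker, local HTTP stub and a toy-dataset generator let the entire
  pipeline run (and be tested) without a network.

## Worked example

```sh
python examples/end_to_end_submission.py
```

generates the toy study (2 samples, 2 paired read sets, a co-assembly of 8
contigs, 3 bins), runs the full submission against the mock services, and
prints:

```
validation errors: 0, taxonomy failures: 0
steps completed: 11/11
accessions assigned: 12
  sample_1                         SAMPLE   ERS0000001
  sample_2                         SAMPLE   ERS0000002
  reads_sample_1                   RUN      ERR0000001
  reads_sample_2                   RUN      ERR0000002
  toy_coassembly_virtual_sample    SAMPLE   ERS0000003
  toy_coassembly                   ANALYSIS ERZ0000001
  bin_1_virtual_sample             SAMPLE   ERS0000004
  bin_1                            ANALYSIS ERZ0000002
  ...
```

11 steps produce 12 accessions: one sample registration step covers both
samples; the co-assembly and every bin additionally receive a *virtual
sample* object carrying the environmental taxon, quality scores and a
"sample derived from" reference back to the physical samples.

The same run from the shell:

```sh
mgbroker makecfg --samples --reads --assembly --bins -o config.yaml
# ... fill the form ...
mgbroker submit config.yaml --samples --reads --assembly --bins \
    --mock --staging-dir staging --summary accessions.tsv
```

Other examples: `examples/resolve_taxonomy.py` (the 543 → 218034 family-level
case), `examples/coverage_and_quality.py` (fold coverage + MIMAG tiers),
`examples/make_template.py` (scenario-specific forms).

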