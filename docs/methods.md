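# Methods

## The submission model

A genome-resolved metagenomics deposition is modelled as a set of **data
levels** — SAMPLES, READS, ASSEMBLY, BINS, MAGS — with a fixed dependency
structure. Sample objects anchor everything: sequencing runs reference a
sample, the assembly references samples and runs, and every derived genome
(bin, MAG) or co-assembly requires its own **virtual sample** object that
carries the environmental taxon and a "sample derived from" attribute
listing the accessions of the physical samples it came from. Execution
order follows this graph strictly: samples → reads → (co-assembly virtual
sample) → assembly → per-bin virtual sample + upload → per-MAG virtual
sample + upload. A receipt is parsed and its accessions recorded in a
write-once ledger before any dependent step runs, so a reference is never
emitted before the object it points to exists.

A **scenario** also records which levels were deposited previously; those
levels contribute no steps, but their accessions seed the ledger, which is
how an existing study is extended. References in the configuration occupy a
single namespace: a string matching an accession pattern
(`(ERS|SAMEA)\d+`, `ERR\d+`, `ERZ\d+`, `(PRJ[EDN][A-Z]\d+|ERP\d+)`) is a
literal, anything else is an alias to be resolved through the ledger.

Each MAG receives a fresh virtual sample rather than reusing its source
bin's. This is the simplest consistent reading of "one virtual sample per
derived object" and it makes the accession arithmetic explicit: a full run
yields `n_samples + n_read_sets + [1 co-assembly] + 1 assembly +
2·n_bins + 2·n_mags` accessions.

On any failed receipt the run aborts and reports the accessions already
assigned; there is no checkpoint/resume in this version — the recovery path
is to re-run the remaining levels in preexisting-accession mode. Transport
failures are retried (3 retries, exponential backoff from 0.5 s) because
they are environmental; rejected receipts are never retried because they
are verdicts on the metadata.

## Coverage

Fold coverage of a reference set is defined as

```
fold = aligned reference-consuming bases / total reference length
```

counting CIGAR operations M, =, X and D (deletions consume reference;
insertions and clips do not) over primary, mapped, non-supplementary
records. This definition is exactly equal to the mean per-position depth,
which is what the property tests assert with rational arithmetic against an
independent pileup oracle. Per-bin coverage restricts both the counted
records and the denominator to the bin's contigs; the same assembly-wide
alignment map therefore serves all bins, though a bin-restricted map works
identically. Inference only happens where the configuration leaves coverage
unset. Manifest values are printed with one decimal (Python's
round-half-even formatting).

## Quality tiers

MIMAG tiers use the completeness/contamination bars only: HIGH iff
completeness > 90 and contamination < 5; MEDIUM iff completeness ≥ 50 and
contamination < 10; else LOW. The rRNA/tRNA presence criteria of the full
standard are deliberately out of scope — they require gene calling by
external tools. A MAG below HIGH yields a validation *warning*, never an
error: the tier is advisory, the researcher decides.

## Environmental taxonomy

Classification tables give ranked lineages (GTDB prefix dialect
`d__…;p__…;…;s__…` or plain semicolon-separated names, normalized onto the
seven canonical ranks). GTDB polyphyletic suffixes (`Escherichia_B`) are
stripped from the trailing token, with a note, because registry records use
base names.

Candidate environmental names derive from the **lowest classified rank**
via a rule table:

| lowest rank | candidates (most specific first) |
|---|---|
| species S | `S`, `uncultured S` |
| genus G | `uncultured G sp.` |
| family/order/class/phylum N | `uncultured N bacterium` / `uncultured N archaeon` (by domain) |
| domain only | `uncultured bacterium` / `uncultured archaeon` |

The table covers Bacteria and Archaea; other domains fail explicitly.
Resolution accepts the first candidate with **exactly one** exact-name,
case-sensitive, *submittable* registry match — superstring suggestions and
rank taxa (e.g. the non-submittable family record 543) are filtered out.
There is deliberately no automatic walk-up to a higher rank after a failed
resolution: silently demoting the rank would change scientific meaning, so
unresolvable genomes are aggregated into a failure list and the submission
refuses to start — zero service interaction — until the user supplies a
`taxonomy_override` or obtains a new taxon identifier. Partial submission
of only the resolvable bins is possible future work; this version halts on
any failure.

## Configuration dialect

The configuration is one YAML document (the registry itself fixes no form
format; YAML supports the inline comments the templates rely on). Mandatory
field tables per level are modelled on public submission-portal
requirements and drive template rendering, parsing and validation from one
source, so the three cannot drift. Unknown keys under any record are
preserved as free attributes and submitted. `collection_date`/`location`
accept the INSDC `missing` keyword, distinguishing "declared missing" from
"omitted". File validation checks existence, non-emptiness and a format
signature on the first record only (FASTA `>`, FASTQ 4-line shape, SAM
header or BAM/BGZF magic); full parsing happens where content is actually
consumed. Paths are stored relative to the configuration file and resolved
on load, keeping datasets relocatable and template/fixture output
deterministic.

Manifest key tables per level (reads: STUDY, SAMPLE, NAME, PLATFORM,
INSTRUMENT, LIBRARY_SOURCE/SELECTION/STRATEGY, FASTQ ×1–2; assembly/bin/
MAG: STUDY, SAMPLE, ASSEMBLYNAME, ASSEMBLY_TYPE, COVERAGE, PROGRAM,
PLATFORM, MOLECULETYPE, FASTA, optional RUN_REF) follow public Webin
conventions; `ASSEMBLY_TYPE` is `primary metagenome`, `binned metagenome`
or `Metagenome-Assembled Genome (MAG)` by level. The assembly record
carries no platform field of its own; PLATFORM is derived as the unique
platforms of the referenced read sets (overridable with an explicit
`platform` key). The virtual-sample attribute vocabulary ("completeness
score", "contamination score", "binning software", "sample derived from")
follows the public binned-metagenome checklist; the checklist identifier is
a parameter (default `ERC000050`), not a constant, because checklists
evolve. XML is serialized with fixed element/attribute order so repeated
runs are byte-identical. During staging, data files are copied (a symlink
option exists); the manifest is rewritten to the staged names.

## Mock services and the toy dataset

The mock registry issues accessions sequentially per object kind with the
same shapes as the patterns above (`ERS0000001`, …), never issues an alias
twice, and answers duplicate or malformed payloads with failure receipts —
it is a server emulation, so it never raises. The taxonomy fixture bundles
the records the resolver's behaviour depends on: `uncultured
Enterobacteriaceae bacterium` (218034), the non-submittable family decoy
`Enterobacteriaceae` (543), `uncultured bacterium` (77133), `uncultured
archaeon` (115547), an archaeal genus entry, a non-submittable superstring
decoy, and deliberately *no* record for one test lineage. Identifiers
verifiable offline are the genuine public ones; entries in the 990000xxx
range are synthetic stand-ins, marked as such in the fixture header. The
same contracts are exposed over a local HTTP stub (with an optional static
bearer-token check) for transport-level tests.

The toy generator emulates a complete small study: random contigs
(240–600 bp), 100-base reads sampled verbatim from them — so every
alignment is a perfect end-to-end match and aligned bases equal
`read records × 100` in closed form — bins partitioning disjoint contig
pairs, a quality table cycling the three MIMAG tiers, and a classification
table containing the family-level Enterobacteriaceae case, an archaeal
genus, a domain-only lineage and one unresolvable lineage. By default the
unresolvable lineage belongs to a genome that is not a configured bin, so
the standard run succeeds; `unresolvable_bin=True` attaches it to the last
bin for halt-path testing. Defaults (2 samples, one paired read set of 20
pairs each, 3 bins, no MAGs) match the typical small co-assembly scenario
the tests are built around. What the generator does **not** emulate:
sequencing error, quality-score variation, chimeric or partial alignments,
realistic genome composition, or registry latency/auth flows — so passing
tests demonstrate the brokering logic, not robustness to messy real-world
alignments (coverage correctness on imperfect CIGARs is covered separately
by the randomized-alignment oracle tests).

## Numerical and degenerate-input choices

Coverage uses integer arithmetic internally (aligned bases, reference
length) and only forms the ratio on demand, so oracle comparisons are
exact. An empty alignment gives fold 0; a header without reference
sequences is an error, as is restricting to unknown contigs. Quality values
are validated to completeness ∈ [0, 100], contamination ≥ 0 at parse time
with row loci. Ledger aliases are write-once; replaying a recorded ledger
reproduces it exactly, including step indices. A dry run executes
everything up to and including staging against placeholder accessions and
returns an empty ledger; taxonomy in a dry run resolves against the bundled
fixture so that document generation needs no network.

## Problem sizes

Tests and the acceptance pathway run at toy scale: 8-contig assemblies,
tens of read pairs, 3 bins, 50 randomized alignment maps for the coverage
oracle. These sizes exercise every code path (co-assembly, all MIMAG tiers,
all resolution outcomes, abort and halt paths) while keeping the whole
suite in seconds; the algorithms themselves are streaming or linear and
have no scale-dependent behaviour.
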