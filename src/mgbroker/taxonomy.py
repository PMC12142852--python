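"""Environmental organism-level taxonomy resolution for bins and MAGs.

Classification pipelines report rank taxa (e.g. the family Enterobacteriaceae,
taxid 543), but an uncultivated genome must be deposited under an
environmental organism-level taxon — for a genome classified at family level
with no genus, that is "uncultured Enterobacteriaceae bacterium" (taxid
218034).  This module derives such candidate names from a ranked lineage and
resolves them against a taxonomy registry, keeping only exact-name matches on
submittable records.

Candidate names are built from the lowest classified rank only; there is no
automatic walk-up to a higher rank after a failed resolution, because silently
demoting the rank changes scientific meaning.  Unresolvable genomes are
reported as failures for the user to fix (a manual taxonomy override, or a
request for a new taxon identifier at the registry).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from .errors import EmptyLineageError, UnsupportedDomainError
from .model import BinRecord, TaxonRecord, TaxonomyAssignment
from .readers import RankedLineage, parse_lineage

_DOMAIN_NOUN = {"Bacteria": "bacterium", "Archaea": "archaeon"}


class TaxonomyQueryClient(Protocol):
    """Contract: a scientific-name query returns matching registry records."""

    def query(self, name: str) -> list[TaxonRecord]: ...


def default_fixture_path() -> Path:
    return Path(str(resources.files("mgbroker").joinpath("data/taxonomy_fixture.tsv")))


def load_taxon_table(path: str | Path) -> list[TaxonRecord]:
    """Load a tab-separated registry table: taxid, scientific_name, rank, submittable."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            taxid, name, rank, submittable = row[:4]
            records.append(TaxonRecord(int(taxid), name, rank,
                                       submittable.strip().lower() == "true"))
    seen = {}
    for r in records:
        key = (r.taxid, r.scientific_name)
        if key in seen:
            raise ValueError(f"duplicate registry record {key}")
        seen[key] = r
    return records


class FixtureTaxonomyClient:
    """Registry client backed by a bundled record table; needs no network.

    Mirrors the behaviour of name-suggestion endpoints: exact matches are
    returned first, then superstring matches (names containing the query),
    which the resolver is expected to filter out.
    """

    def __init__(self, path: str | Path | None = None):
        self.records = load_taxon_table(path or default_fixture_path())

    def query(self, name: str) -> list[TaxonRecord]:
        exact = [r for r in self.records if r.scientific_name == name]
        superstrings = [r for r in self.records
                        if name in r.scientific_name and r.scientific_name != name]
        return exact + superstrings


def candidate_names(lineage: RankedLineage) -> list[str]:
    """Environmental-taxon name candidates from the lowest classified rank.

    Species S -> [S, "uncultured S"]; genus G -> ["uncultured G sp."];
    family/order/class/phylum N -> ["uncultured N bacterium|archaeon"]
    (noun by domain); domain only -> ["uncultured bacterium|archaeon"].
    Ordered most specific first.
    """
    lowest = lineage.lowest()
    if lowest is None:
        raise EmptyLineageError("all ranks are empty; no candidate name derivable")
    if lineage.domain not in _DOMAIN_NOUN:
        raise UnsupportedDomainError(
            f"domain {lineage.domain!r} is outside the Bacteria/Archaea rule table")
    rank, name = lowest
    noun = _DOMAIN_NOUN[lineage.domain]
    if rank == "species":
        return [name, f"uncultured {name}"]
    if rank == "genus":
        return [f"uncultured {name} sp."]
    if rank == "domain":
        return [f"uncultured {noun}"]
    return [f"uncultured {name} {noun}"]


@dataclass
class ResolutionFailure:
    """A genome whose environmental taxon could not be resolved."""

    bin_id: str
    tried: list[str]
    reason: str

    def __str__(self) -> str:
        tried = ", ".join(repr(t) for t in self.tried) or "nothing"
        return f"{self.bin_id}: {self.reason} (tried: {tried})"


def resolve_taxonomy(candidates: Sequence[str], client: TaxonomyQueryClient,
                     rank_used: str = "NONE") -> TaxonomyAssignment | ResolutionFailure:
    """Resolve the first candidate with exactly one exact submittable match.

    Name matching is exact and case-sensitive; superstring suggestions are
    discarded.  Returns a ``ResolutionFailure`` carrying the tried names when
    no candidate resolves.  Transport errors from the client propagate — they
    are retriable conditions, not resolution failures.
    """
    if not candidates:
        raise EmptyLineageError("no candidate names to resolve")
    for name in candidates:
        hits = [r for r in client.query(name)
                if r.scientific_name == name and r.submittable]
        if len(hits) == 1:
            return TaxonomyAssignment(name, hits[0].taxid,
                                      source="RESOLVED", rank_used=rank_used)
    return ResolutionFailure("", list(candidates),
                             "no submittable exact match in the taxonomy registry")


def resolve_all(
    bins: Iterable[BinRecord],
    client: TaxonomyQueryClient,
    overrides: Mapping[str, TaxonomyAssignment] | None = None,
) -> tuple[dict[str, TaxonomyAssignment], list[ResolutionFailure]]:
    """Resolve every bin/MAG; aggregate failures instead of raising one-by-one.

    User overrides bypass the registry entirely (source=USER).  The returned
    failure list is what the orchestrator uses to refuse submission.
    """
    overrides = dict(overrides or {})
    assignments: dict[str, TaxonomyAssignment] = {}
    failures: list[ResolutionFailure] = []
    for b in bins:
        override = overrides.get(b.bin_id) or b.taxonomy_override
        if override is not None:
            assignments[b.bin_id] = TaxonomyAssignment(
                override.scientific_name, override.taxid,
                source="USER", rank_used=override.rank_used)
            continue
        if not b.lineage:
            failures.append(ResolutionFailure(
                b.bin_id, [], "no classification and no taxonomy override"))
            continue
        try:
            lineage = parse_lineage(b.lineage)
            names = candidate_names(lineage)
        except (EmptyLineageError, UnsupportedDomainError) as exc:
            failures.append(ResolutionFailure(b.bin_id, [], str(exc)))
            continue
        rank = lineage.lowest()[0]
        outcome = resolve_taxonomy(names, client, rank_used=rank)
        if isinstance(outcome, ResolutionFailure):
            outcome.bin_id = b.bin_id
            failures.append(outcome)
        else:
            assignments[b.bin_id] = outcome
    return assignments, failures
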