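"""Derive and resolve an environmental organism-level taxon for a bin.

Classification pipelines report rank taxa (a family, a genus, ...), but an
uncultivated genome must be deposited under an environmental taxon such as
"uncultured Enterobacteriaceae bacterium".  This script walks the classic
family-level case through candidate-name derivation and registry resolution.
"""

from mgbroker import candidate_names, parse_lineage, resolve_taxonomy
from mgbroker.taxonomy import FixtureTaxonomyClient

lineage = parse_lineage(
    "d__Bacteria;p__Pseudomonadota;c__Gammaproteobacteria;"
    "o__Enterobacterales;f__Enterobacteriaceae;g__;s__")
print(f"lowest classified rank: {lineage.lowest()}")

names = candidate_names(lineage)
print(f"candidate environmental names: {names}")

assignment = resolve_taxonomy(names, FixtureTaxonomyClient(),
                              rank_used=lineage.lowest()[0])
print(f"resolved: {assignment.scientific_name} (taxid {assignment.taxid}, "
      f"from the {assignment.rank_used} rank)")
# The taxid is the identifier the registry expects on the bin's virtual
# sample object; the family rank taxon itself (543) is not submittable.
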