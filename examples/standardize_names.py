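"""Standardize messy organism names and resolve them to NCBI TAXIDs.

Builds a miniature taxonomy-dump index, then annotates a list of names
as they typically arrive from profiler output: strain tags, bracketed
tentative genera, subspecies qualifiers and serotype suffixes.
"""

import tempfile
from pathlib import Path

from taxabench import (
    AbundanceProfile,
    TaxonRecord,
    annotate_taxids,
    apply_curations,
    build_taxonomy_index,
    generate_mini_taxdump,
    load_curations,
    standardize_name,
)
from taxabench.simulate import SPECIES_POOL

names = [
    "Marinobacter sp. LV10R510-8",
    "[Clostridium] innocuum",
    "Escherichia coli",
    "Escherichia",
]
print("standardized forms:")
for name in names:
    print(f"  {name!r:40s} -> {standardize_name(name)}")

with tempfile.TemporaryDirectory() as td:
    names_dmp, nodes_dmp = Path(td) / "names.dmp", Path(td) / "nodes.dmp"
    generate_mini_taxdump(SPECIES_POOL, names_dmp, nodes_dmp)
    index = build_taxonomy_index(names_dmp, nodes_dmp, source_version="mini")
    resolved = annotate_taxids(["Escherichia coli", "[Clostridium] innocuum"], index)
    print("\nTAXIDs resolved through the index:")
    for name, taxid in resolved.items():
        print(f"  {name!r:30s} -> {taxid}")

# curation rules: the serotype is folded into its species-level TAXID, and
# a subspecies merge sums relative abundances (24% + 13% -> 37%)
profile = AbundanceProfile(
    "demo", "demo",
    [
        TaxonRecord("Escherichia coli O157:H7", 83334, 63.0),
        TaxonRecord("Bifidobacterium longum subsp. longum", None, 24.0),
        TaxonRecord("Bifidobacterium longum", 216816, 13.0),
    ],
)
curated = apply_curations(profile, load_curations())
print("\nafter curation rules:")
for r in curated.records:
    print(f"  {r.name:30s} taxid={r.taxid}  {r.rel_abund:.1f}%")
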