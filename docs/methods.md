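# Methods

This note documents the models, conventions and numerical choices behind
`taxabench`, and what its synthetic tests do and do not demonstrate
about real data.

## Name standardization

Profilers and databases disagree on organism spelling, so cross-pipeline
comparison is keyed on NCBI TAXIDs resolved through a standardized-name
index. The standardization rule is deterministic and idempotent: split
on whitespace; strip `[` `]` from the first (genus) token; in every
later token replace characters outside letters, digits, `.` and `-`
with `-`; join with `_`; uppercase. The replacement alphabet
deliberately preserves `.` and digit/hyphen strain tags
(`Marinobacter sp. LV10R510-8 → MARINOBACTER_SP._LV10R510-8`); a stricter
"letters only" rule would destroy strain identifiers and make round-trip
resolution impossible. Single-word names (genus and higher ranks) are
only uppercased. A useful consequence: space-separated and
underscore-joined spellings of the same name standardize to the same
key, so clade-string species names need no special casing.

Index construction reads `names.dmp` (all name classes). When two dump
records standardize to the same key, the scientific-name record wins;
ties fall to the lowest TAXID, and every collision is logged and kept in
`TaxonomyIndex.collisions` for auditing. The index persists as a
versioned two-column TSV rather than an opaque binary so diffs are
reviewable; `merged.dmp` is honored when supplied (retired ids remapped
before indexing) and ignored otherwise. Strain-level dump entries are
indexed as-is — collapsing them to species parents would require tree
traversal, which is out of scope; species-level resolution of strain
names is instead handled by the standardizer keeping strain tags intact
plus curation rules where a dataset needs them.

Curation rules are data, not code: `rename` (spelling/clade fixes),
`reclassify` (subspecies/serotype → species-level name and TAXID) and
`merge` (fold one taxon into another, summing abundances, conserving the
total exactly). The bundled defaults cover the recurring cases in public
mock-community work: the Prevotella copri clade-A rename, the
Clostridium clostridiiforme spelling fix, species-level
reclassification of Salmonella enterica subsp. enterica (59201 → 28901)
and Escherichia coli O157:H7 (83334 → 562), and the merge of
Bifidobacterium longum subsp. longum into its species.

## Abundance representation

Percent (0–100) is the canonical unit everywhere; proportions appear
only transiently inside the CLR transform, which is scale-invariant, so
the choice is cosmetic for AD but keeps tables directly comparable with
published numbers. Dialect conventions: marker-gene profiles carry no
unclassified fraction (`None`, not 0 — absence of evidence); count
reports express species as percent of *classified* counts with the
unclassified percentage carried separately; long tables treat rows
classified only above species rank as unclassified and add them to the
`Unclassified` row. Dialects are named by the caller — auto-detection
is deliberately not attempted.

## Metrics

**Join semantics.** Expected and observed profiles are union-joined on
TAXID, absent sides coded 0. The union (not an expected-left join) is
essential: the Aitchison distance must be penalized for extraneous
species, and FPRA needs the observed-only rows. The qualitative heatmap
export uses the expected-left join, unfiltered, with log10 abundances
and empty cells for zeros.

**False-positive filter.** Before any metric, false-positive taxa
observed below 0.01% are dropped. Only rows with zero expected
abundance are ever removed; an expected taxon observed below the
threshold still counts as a sensitivity hit. The threshold is
configurable because no single filtering level is right for every
application.

**Aitchison distance.** Each vector over the (post-filter) union taxon
set is closed to proportions; zeros are imputed by multiplicative
replacement with `delta = (1/D)²` (the convention of the reference
implementation of these transforms), which assigns `delta` to each zero
and shrinks the non-zeros by `1 − delta·z` so closure is preserved
exactly; then CLR and Euclidean distance. Closing each vector to 1
rather than leaving raw percentages is documented but immaterial: CLR is
scale-invariant, so it changes nothing once the union set is fixed.
`delta·z ≥ 1` (too many zeros for the chosen delta) is an error rather
than a silent degenerate result; with the default delta it cannot occur.

**Sensitivity and FPRA.** Sensitivity = 100 · (taxa with expected > 0
and observed > 0) / (taxa with expected > 0), after filtering.
FPRA = 100 · Σ observed over expected-zero rows / Σ observed, over
annotated species only — the unclassified fraction is never a false
positive, and overestimating an expected taxon contributes nothing.
Unclassified mass is likewise excluded from the AD composition: two of
the supported dialects cannot report it, and including it would make AD
incomparable across pipelines.

## Confusion-matrix analysis

Panels with known per-sample presence/absence allow organism-centric
scoring. Calls use strict inequalities (`> threshold` is positive,
`≤ threshold` negative), so at the 0% threshold a species reported at
literally 0% counts as not observed. Raising the threshold can only
move calls toward the negative side (TN never becomes FP, FN never
becomes TP) — a property test guards this. Expected values inside
`(0, threshold]` would make TP-vs-FN ambiguous; they trigger a warning
rather than a silent call. Scores with zero denominators are missing
(NaN), never 0; in particular specificity with TN+FP = 0 is missing,
not 1. Aggregation across organisms uses the harmonic mean over
non-missing values by default; a stricter `drop_organism` mode (remove
an organism everywhere if any pipeline is missing it) is provided as a
cross-check — on the bundled reference panel the two agree to within a
few thousandths. Accuracy is computed and exported alongside the other
scores even though published tables rarely print it.

## Statistics

Summaries are mean ± SD per (community, pipeline, metric); SD is absent
for single-sample communities. The community average across pipelines
serves as a difficulty score; the pipeline average across communities is
the unweighted grand mean. Cross-pipeline comparison: Kruskal–Wallis
(tie-corrected, chi-square approximation, df = k−1; identical data
short-circuits to H = 0, p = 1), then all pairwise two-sample rank tests
with Benjamini–Hochberg adjustment. The default sampling unit is the
per-community mean — that is the level at which published summaries are
fully printed — with a switch to per-sample values. The default
pairwise test is the unpaired rank-sum; the paired signed-rank variant
is available when samples genuinely correspond. Exact small-sample
p-values are used when the pooled size is ≤ 10 and tie-free, the
tie-corrected normal approximation otherwise. A pair that cannot be
tested (group of size 1) is recorded with NaN rather than aborting the
whole family.

## Synthetic data

The generator emulates the error structure the metrics are designed to
measure, with exact bookkeeping (`GeneratorTruth`). Designs: *even*
(100/n each, mirroring ~20-species even DNA mixtures), *staggered*
(geometric series with jittered exponents spanning ≥ 4 orders of
magnitude — chosen over resampling real compositions for analytic
control of dynamic range), and a *Latin-square panel* (five samples:
one with every block, four each omitting one block, a control block
present everywhere — giving every non-control organism exactly one known
true-negative sample). Corruption: independent per-taxon dropout;
injected false-positive taxa with fresh TAXIDs above the real-id range
carrying a configured total mass; multiplicative log-normal noise
applied before renormalization to 100%; and optional name corruption
(strain suffixes, brackets, subspecies tags, underscore spellings) to
exercise the standardizer. Defaults (20 species, 10% dropout, 5 false
positives at 5% mass, σ = 0.2) sit in the range real pipelines exhibit
on gut-microbiome mocks.

Noise-free invariants: sensitivity equals 100·(kept/expected) exactly;
FPRA equals the injected mass exactly (profiles are renormalized to
100%); identity corruption gives AD = 0. With noise, truth predictions
hold in expectation. All randomness flows through one seeded
`numpy.random.default_rng` (PCG64); a fixed seed reproduces a bundle
bit-for-bit across platforms.

What passing synthetic tests does **not** show: real profilers' errors
are not independent per taxon (confusions are phylogenetically
structured — near-identical genomes like E. coli/Shigella are mistaken
for each other systematically), false-positive abundance is heavy-tailed
rather than near-uniform, abundance bias correlates with genome size and
database coverage, and name drift in real databases is richer than the
four corruption modes. The synthetic layer validates the *evaluation
machinery*, not any claim about how a particular pipeline performs.

## Reference tables and problem sizes

The bundled TSVs carry the per-community mean metric cells and
per-organism F1 cells of a published five-pipeline benchmark, printed at
2–3 decimals. Aggregates recomputed from them therefore match published
grand averages to the printed precision, but harmonic means recomputed
from 3-decimal F1 cells can sit ~10⁻³ from aggregates computed on full
precision — tests account for that. The acceptance script's
parameter-recovery runs use 200 taxa × 100 replicates for the dropout
check and 20 taxa for the exact-recovery checks; these sizes give
binomial standard errors well below the asserted tolerances while
keeping the whole script in the seconds range.

## Known limitations

* No phylogeny-aware distances (UniFrac and relatives), by design.
* No lineage reconstruction or LCA: the taxonomy layer is a flat
  name → TAXID map.
* Spreadsheet workbooks are not parsed; export to TSV first.
* The count-report column layout is a declared stand-in — real k-mer
  classifier reports vary, and users with a different layout should use
  the long-table dialect.
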