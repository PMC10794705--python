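"""Synthetic mock communities, corrupted observed profiles and mini
taxonomy dumps.

Real benchmark inputs are sequencing runs pushed through heavyweight
profiling pipelines; nothing in the evaluation layer needs that.  This
module emulates the error structure the metrics are designed to detect —
per-taxon dropout, spurious false-positive taxa carrying a configured
abundance mass, multiplicative log-normal abundance noise, replicate
structure, and the organism-name variants (strain tags, bracketed
genera, subspecies qualifiers) that exercise the name standardizer —
with exact bookkeeping, so every metric has a known ground-truth value.

All randomness flows through one seeded NumPy generator
(:func:`numpy.random.default_rng`, PCG64), so a fixed seed reproduces a
bundle bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import DegenerateInputError, ValidationError
from .profiles import (
    AbundanceProfile,
    ExpectedComposition,
    TaxonRecord,
    write_expected,
)

#: (TAXID, scientific name) pool the generator draws community members from.
#: Gut-associated and clinical species mirroring the organisms mock
#: communities are typically built from; ids are genuine NCBI TAXIDs.
SPECIES_POOL: list[tuple[int, str]] = [
    (562, "Escherichia coli"),
    (28901, "Salmonella enterica"),
    (1639, "Listeria monocytogenes"),
    (1280, "Staphylococcus aureus"),
    (573, "Klebsiella pneumoniae"),
    (1351, "Enterococcus faecalis"),
    (446, "Legionella pneumophila"),
    (487, "Neisseria meningitidis"),
    (624, "Shigella sonnei"),
    (644, "Aeromonas hydrophila"),
    (85698, "Achromobacter xylosoxidans"),
    (470, "Acinetobacter baumannii"),
    (1314, "Streptococcus pyogenes"),
    (29494, "Vibrio furnissii"),
    (216816, "Bifidobacterium longum"),
    (817, "Bacteroides fragilis"),
    (818, "Bacteroides thetaiotaomicron"),
    (853, "Faecalibacterium prausnitzii"),
    (1522, "[Clostridium] innocuum"),
    (165179, "Prevotella copri"),
    (2173, "Methanobrevibacter smithii"),
    (39491, "[Eubacterium] rectale"),
    (1496, "Clostridioides difficile"),
    (74426, "Collinsella aerofaciens"),
    (239935, "Akkermansia muciniphila"),
    (823, "Parabacteroides distasonis"),
    (166486, "Roseburia intestinalis"),
    (28116, "Bacteroides ovatus"),
    (820, "Bacteroides uniformis"),
    (1304, "Streptococcus salivarius"),
    (1590, "Lactiplantibacillus plantarum"),
    (1613, "Limosilactobacillus fermentum"),
]

#: false-positive taxa get fresh ids far above the real-taxon range
FP_TAXID_BASE = 9_000_000

NAME_CORRUPTIONS = ("strain_suffix", "brackets", "subspecies", "spelling_variant")

DESIGNS = ("even", "staggered", "latin_square_panel")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults emulate the common mock-community setup: a 20-species even
    DNA mixture, mild per-taxon dropout, a handful of spurious taxa
    carrying a few percent of the signal, and moderate multiplicative
    abundance noise.
    """

    seed: int = 0
    n_species: int = 20
    design: str = "even"
    dropout_prob: float = 0.1
    n_false_positives: int = 5
    fp_mass_pct: float = 5.0
    noise_sigma: float = 0.2
    n_replicates: int = 1
    name_corruption: tuple[str, ...] = ()

    def validate(self) -> "SimulationConfig":
        if self.n_species < 2:
            raise ValidationError("n_species must be >= 2")
        if self.design not in DESIGNS:
            raise ValidationError(f"design must be one of {DESIGNS}")
        if not 0 <= self.dropout_prob < 1:
            raise ValidationError("dropout_prob must be in [0, 1)")
        if self.n_false_positives < 0:
            raise ValidationError("n_false_positives must be >= 0")
        if not 0 <= self.fp_mass_pct < 100:
            raise ValidationError("fp_mass_pct must be in [0, 100)")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        unknown = set(self.name_corruption) - set(NAME_CORRUPTIONS)
        if unknown:
            raise ValidationError(f"unknown name corruption(s): {sorted(unknown)}")
        return self


@dataclass
class ReplicateTruth:
    """Exact bookkeeping for one simulated replicate."""

    dropped: set[int]
    fp_masses: dict[int, float]  # taxid -> injected percent (pre-noise)
    noise_multipliers: dict[int, float]
    name_map: dict[int, str]  # taxid -> (possibly corrupted) rendered name


@dataclass
class GeneratorTruth:
    """Bookkeeping for all replicates of one simulated sample.

    Sufficient to predict sensitivity and FPRA exactly before noise is
    applied, and every metric in expectation afterwards.
    """

    community_id: str
    n_expected: int
    replicates: list[ReplicateTruth] = field(default_factory=list)

    def predicted_sensitivity(self, replicate: int) -> float:
        rep = self.replicates[replicate]
        return 100.0 * (self.n_expected - len(rep.dropped)) / self.n_expected

    def predicted_fpra(self, replicate: int) -> float:
        # profiles are renormalized to 100%, so the injected FP mass is
        # exactly the FPRA (noise-free case)
        return float(sum(self.replicates[replicate].fp_masses.values()))


#: synthetic taxa extend the pool when a community is larger than it
SYNTH_TAXID_BASE = 1_000_000


def _pick_taxa(config: SimulationConfig, rng: np.random.Generator):
    if config.n_species <= len(SPECIES_POOL):
        idx = rng.choice(len(SPECIES_POOL), size=config.n_species, replace=False)
        return [SPECIES_POOL[i] for i in sorted(idx)]
    extra = [
        (SYNTH_TAXID_BASE + i, f"Synthetica species-{i}")
        for i in range(config.n_species - len(SPECIES_POOL))
    ]
    return list(SPECIES_POOL) + extra


def generate_expected(config: SimulationConfig) -> ExpectedComposition:
    """Generate a ground-truth community for the even or staggered design.

    Even: every taxon at 100/n percent.  Staggered: abundances follow a
    geometric series with jittered exponents spanning more than four
    orders of magnitude, mirroring staggered DNA mixtures.  For the
    multi-sample latin-square design use :func:`generate_panel`.
    """
    config.validate()
    if config.design == "latin_square_panel":
        raise ValidationError(
            "latin_square_panel is a multi-sample design; use generate_panel()"
        )
    rng = np.random.default_rng(config.seed)
    taxa = _pick_taxa(config, rng)
    n = config.n_species
    if config.design == "even":
        pcts = np.full(n, 100.0 / n)
    else:
        exponents = np.linspace(0.0, 4.5, n) + rng.uniform(-0.2, 0.2, size=n)
        weights = 10.0 ** exponents
        pcts = 100.0 * weights / weights.sum()
    records = [
        TaxonRecord(name, taxid, float(p)) for (taxid, name), p in zip(taxa, pcts)
    ]
    return ExpectedComposition(f"sim-{config.design}-{config.seed}", records)


def generate_panel(
    config: SimulationConfig, n_blocks: int = 5
) -> dict[str, ExpectedComposition]:
    """Latin-square-style presence/absence panel.

    Taxa are split into ``n_blocks`` blocks; the last block is an internal
    control present in every sample.  The panel holds one even sample
    (``EG``, all blocks present) plus one sample per non-control block in
    which that block is absent and the remaining blocks are diluted over
    log steps.  Every non-control organism is therefore absent from
    exactly one sample — the known true negatives the confusion-matrix
    analysis requires.
    """
    config.validate()
    if config.n_species < n_blocks:
        raise ValidationError("need at least one species per block")
    rng = np.random.default_rng(config.seed)
    taxa = _pick_taxa(config, rng)
    blocks = [list(taxa[i::n_blocks]) for i in range(n_blocks)]
    control = blocks[-1]
    panel: dict[str, ExpectedComposition] = {}

    def build(sample_id: str, omit: Optional[int], dilutions: Sequence[float]):
        records = []
        weights = []
        for b, block in enumerate(blocks):
            if b == omit:
                continue
            for taxid, name in block:
                records.append((taxid, name))
                weights.append(dilutions[b])
        w = np.asarray(weights, dtype=float)
        pcts = 100.0 * w / w.sum()
        panel[sample_id] = ExpectedComposition(
            sample_id,
            [TaxonRecord(n_, t, float(p)) for (t, n_), p in zip(records, pcts)],
        )

    build("EG", None, [1.0] * n_blocks)
    for b in range(n_blocks - 1):
        # remaining non-control blocks diluted over log steps; control at 1e-2
        dil = [10.0 ** -((b + k) % (n_blocks - 1)) for k in range(n_blocks - 1)]
        dil.append(1e-2)
        build(f"MIX-{chr(ord('A') + b)}", b, dil)
    return panel


def _corrupt_name(
    name: str, kinds: tuple[str, ...], rng: np.random.Generator, taxid: int
) -> str:
    if not kinds or rng.random() < 0.5:
        return name
    kind = kinds[int(rng.integers(len(kinds)))]
    tokens = name.split()
    if kind == "strain_suffix":
        return f"{name} str. TB-{taxid % 997}"
    if kind == "brackets" and not name.startswith("["):
        return f"[{tokens[0]}] {' '.join(tokens[1:])}" if len(tokens) > 1 else f"[{name}]"
    if kind == "subspecies" and len(tokens) >= 2:
        return f"{name} subsp. {tokens[-1]}"
    if kind == "spelling_variant":
        return name.replace(" ", "_")
    return name


def simulate_observed(
    expected: ExpectedComposition,
    config: SimulationConfig,
    pipeline_id: str = "sim-pipeline",
) -> tuple[list[AbundanceProfile], GeneratorTruth]:
    """Corrupt a ground-truth community into observed replicate profiles.

    Per replicate: each expected taxon is independently dropped with
    ``dropout_prob``; ``n_false_positives`` novel taxa are injected
    carrying ``fp_mass_pct`` percent of the total; every retained
    abundance is multiplied by exp(N(0, sigma^2)); and the profile is
    renormalized to 100%.  Bookkeeping of every corruption is returned.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # decoupled from design draw
    truth = GeneratorTruth(expected.community_id, len(expected.records))
    profiles = []
    for rep in range(config.n_replicates):
        keep_mask = rng.random(len(expected.records)) >= config.dropout_prob
        if not keep_mask.any():
            raise DegenerateInputError(
                f"replicate {rep}: every taxon dropped; lower dropout_prob"
            )
        survivors = [r for r, k in zip(expected.records, keep_mask) if k]
        dropped = {r.taxid for r, k in zip(expected.records, keep_mask) if not k}

        fp_masses: dict[int, float] = {}
        fp_records: list[TaxonRecord] = []
        fp_total = config.fp_mass_pct if config.n_false_positives > 0 else 0.0
        if config.n_false_positives > 0:
            raw = rng.random(config.n_false_positives) + 0.5
            masses = fp_total * raw / raw.sum()
            for i, mass in enumerate(masses):
                taxid = FP_TAXID_BASE + rep * 1000 + i
                name = f"Contaminantus simulatus FP-{rep}-{i}"
                fp_masses[taxid] = float(mass)
                fp_records.append(TaxonRecord(name, taxid, float(mass)))

        surv_total = sum(r.rel_abund for r in survivors)
        scale = (100.0 - fp_total) / surv_total
        base = [
            TaxonRecord(r.name, r.taxid, r.rel_abund * scale) for r in survivors
        ] + fp_records

        noise_mult = {
            r.taxid: (
                float(np.exp(rng.normal(0.0, config.noise_sigma)))
                if config.noise_sigma > 0
                else 1.0
            )
            for r in base
        }
        noisy = np.array([r.rel_abund * noise_mult[r.taxid] for r in base])
        noisy = 100.0 * noisy / noisy.sum()

        name_map = {
            r.taxid: _corrupt_name(r.name, config.name_corruption, rng, r.taxid)
            for r in base
        }
        records = [
            TaxonRecord(name_map[r.taxid], r.taxid, float(p))
            for r, p in zip(base, noisy)
        ]
        profiles.append(
            AbundanceProfile(
                sample_id=f"{expected.community_id}-rep{rep}",
                pipeline_id=pipeline_id,
                records=records,
            )
        )
        truth.replicates.append(
            ReplicateTruth(dropped, fp_masses, noise_mult, name_map)
        )
    return profiles, truth


# ---------------------------------------------------------------------------
# mini taxonomy dump


def generate_mini_taxdump(
    taxa: Sequence[tuple[int, str]],
    names_path: Union[str, Path],
    nodes_path: Union[str, Path],
    synonyms: Sequence[tuple[int, str]] = (),
) -> None:
    """Write taxdump-dialect names/nodes files for the given taxa.

    ``taxa`` rows become scientific-name records; ``synonyms`` become
    synonym-class records (useful for registering corrupted name variants
    against their true TAXID).  Duplicate TAXIDs in ``taxa`` are an error.
    """
    ids = [t for t, _ in taxa]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate TAXIDs in mini taxdump: {dupes}")
    if not taxa:
        warnings.warn("writing an empty mini taxdump")
    name_lines = [
        f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|" for taxid, name in taxa
    ]
    name_lines += [
        f"{taxid}\t|\t{name}\t|\t\t|\tsynonym\t|" for taxid, name in synonyms
    ]
    node_lines = [f"{taxid}\t|\t1\t|\tspecies\t|" for taxid, _ in taxa]
    Path(names_path).write_text("\n".join(name_lines) + ("\n" if name_lines else ""))
    Path(nodes_path).write_text("\n".join(node_lines) + ("\n" if node_lines else ""))


# ---------------------------------------------------------------------------
# dialect renderers (inverses of the profiles.py parsers)

_FAKE_LINEAGE = "k__Bacteria|p__SimPhylum|c__SimClass|o__SimOrder|f__SimFamily"


def render_dialect(profile: AbundanceProfile, dialect: str) -> str:
    """Render a profile as dialect text; parse_profile inverts it exactly."""
    if dialect == "marker_profile":
        lines = ["#taxonomy\trelative_abundance"]
        for r in profile.records:
            species = r.name.replace(" ", "_")
            genus = species.split("_")[0].strip("[]")
            clade = f"{_FAKE_LINEAGE}|g__{genus}|s__{species}"
            lines.append(f"{clade}\t{r.rel_abund!r}")
        return "\n".join(lines) + "\n"
    if dialect == "count_report":
        lines = []
        if profile.unclassified_pct is not None:
            lines.append(f"Unclassified\t{profile.unclassified_pct!r}%")
        for r in profile.records:
            if r.taxid is None:
                raise ValidationError(f"count_report needs TAXIDs ({r.name!r})")
            lines.append(f"{r.name}\t{r.taxid}\t{r.rel_abund!r}")
        return "\n".join(lines) + "\n"
    if dialect == "ogu_table":
        lines = []
        for r in profile.records:
            if r.taxid is None:
                raise ValidationError(f"ogu_table needs TAXIDs ({r.name!r})")
            lines.append(f"{r.taxid}\t{r.rel_abund!r}\t{r.name}")
        return "\n".join(lines) + "\n"
    if dialect == "long_table":
        lines = ["name\ttaxid\trel_abund\tsample_id"]
        for r in profile.records:
            taxid = "" if r.taxid is None else str(r.taxid)
            lines.append(f"{r.name}\t{taxid}\t{r.rel_abund!r}\t{profile.sample_id}")
        if profile.unclassified_pct is not None:
            lines.append(
                f"Unclassified\t\t{profile.unclassified_pct!r}\t{profile.sample_id}"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unsupported dialect {dialect!r}")


def write_bundle(config: SimulationConfig, outdir: Union[str, Path]) -> Path:
    """Simulate a full input bundle on disk: expected table, observed
    profiles in every dialect, a mini taxdump covering every rendered
    name, and a truth manifest TSV.

    Returns the bundle directory.
    """
    from .profiles import DIALECTS  # local import to keep module load light

    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expected = generate_expected(config)
    write_expected(expected, outdir / "expected.tsv")
    profiles, truth = simulate_observed(expected, config)

    seen: dict[int, str] = {t: n for t, n in SPECIES_POOL}
    synonyms: list[tuple[int, str]] = []
    manifest = ["replicate\ttaxid\tname\tstatus\tvalue"]
    for rep_i, (profile, rep) in enumerate(zip(profiles, truth.replicates)):
        for dialect in DIALECTS:
            path = outdir / f"observed-rep{rep_i}.{dialect}.tsv"
            path.write_text(render_dialect(profile, dialect))
        for taxid, name in rep.name_map.items():
            if taxid not in seen:
                seen[taxid] = name
            elif name != seen[taxid]:
                synonyms.append((taxid, name))
        for taxid in rep.dropped:
            manifest.append(f"{rep_i}\t{taxid}\t\tdropped\t")
        for taxid, mass in rep.fp_masses.items():
            manifest.append(f"{rep_i}\t{taxid}\t{rep.name_map[taxid]}\tfalse_positive\t{mass!r}")
        manifest.append(
            f"{rep_i}\t\t\tpredicted_sensitivity\t{truth.predicted_sensitivity(rep_i)!r}"
        )
        manifest.append(f"{rep_i}\t\t\tpredicted_fpra\t{truth.predicted_fpra(rep_i)!r}")
    generate_mini_taxdump(
        sorted(seen.items()),
        outdir / "names.dmp",
        outdir / "nodes.dmp",
        synonyms=sorted(set(synonyms)),
    )
    (outdir / "truth_manifest.tsv").write_text("\n".join(manifest) + "\n")
    return outdir
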