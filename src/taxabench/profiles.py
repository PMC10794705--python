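"""Normalized abundance containers and parsers for profiler-output dialects.

Every supported profiler writes species-level output in its own shape:
marker-gene profilers emit ranked clade strings with relative abundances,
k-mer classifiers emit count reports with an optional leading
"Unclassified" line, OGU classifiers emit (TAXID, count, name) triples,
and ground-truth/expected tables arrive as generic long-format TSVs.
All of them are normalized here into :class:`AbundanceProfile` /
:class:`ExpectedComposition`, with relative abundances always expressed
in percent (0-100).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .exceptions import (
    DegenerateInputError,
    ProfileParseError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathOrBuffer = Union[str, Path, io.TextIOBase]

#: dialect identifiers accepted by parse_profile / render_dialect
DIALECTS = ("marker_profile", "count_report", "ogu_table", "long_table")

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class TaxonRecord:
    """One observed taxon: free-form or standardized name, optional TAXID,
    relative abundance in percent."""

    name: str
    taxid: Optional[int]
    rel_abund: float

    def __post_init__(self):
        if self.rel_abund < 0:
            raise ValidationError(
                f"negative relative abundance for {self.name!r}: {self.rel_abund}"
            )
        if self.taxid is not None and self.taxid < 1:
            raise ValidationError(f"TAXID must be >= 1, got {self.taxid}")


@dataclass
class AbundanceProfile:
    """One sample's species-level relative abundances from one pipeline.

    ``unclassified_pct`` is ``None`` for dialects that do not report an
    unclassified fraction (marker-gene profiles), otherwise the percent of
    signal left unannotated at species level.
    """

    sample_id: str
    pipeline_id: str
    records: list[TaxonRecord] = field(default_factory=list)
    unclassified_pct: Optional[float] = None

    def total(self) -> float:
        """Sum of classified relative abundances, in percent."""
        return float(sum(r.rel_abund for r in self.records))

    def validate(self) -> "AbundanceProfile":
        classified = self.total()
        uncl = self.unclassified_pct or 0.0
        if uncl < 0 or uncl > 100:
            raise ValidationError(f"unclassified_pct out of range: {uncl}")
        if classified + uncl > 100 + _SUM_TOL:
            raise ValidationError(
                f"classified ({classified:.6f}%) + unclassified ({uncl:.6f}%) "
                "exceed 100%"
            )
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.records],
                "taxid": [r.taxid for r in self.records],
                "rel_abund": [r.rel_abund for r in self.records],
            }
        )

    def by_taxid(self) -> dict[int, TaxonRecord]:
        out: dict[int, TaxonRecord] = {}
        for r in self.records:
            if r.taxid is None:
                raise ValidationError(f"record {r.name!r} has no TAXID")
            if r.taxid in out:
                raise ValidationError(f"duplicate TAXID {r.taxid} in profile")
            out[r.taxid] = r
        return out

    def with_records(self, records: Iterable[TaxonRecord]) -> "AbundanceProfile":
        return replace(self, records=list(records))


@dataclass
class ExpectedComposition:
    """Ground-truth relative abundances for one mock community."""

    community_id: str
    records: list[TaxonRecord] = field(default_factory=list)

    def validate(self) -> "ExpectedComposition":
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(
                f"duplicate taxa in community {self.community_id!r}: {dupes}"
            )
        for r in self.records:
            if r.rel_abund <= 0:
                raise ValidationError(
                    f"expected taxon {r.name!r} listed at {r.rel_abund}%; "
                    "expected abundances must be positive"
                )
        total = self.total()
        if not 99.0 <= total <= 101.0:
            raise ValidationError(
                f"community {self.community_id!r} sums to {total:.4f}%, "
                "outside [99, 101]"
            )
        return self

    def total(self) -> float:
        return float(sum(r.rel_abund for r in self.records))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.records],
                "taxid": [r.taxid for r in self.records],
                "expected_pct": [r.rel_abund for r in self.records],
            }
        )

    def by_taxid(self) -> dict[int, TaxonRecord]:
        out: dict[int, TaxonRecord] = {}
        for r in self.records:
            if r.taxid is None:
                raise ValidationError(f"expected taxon {r.name!r} has no TAXID")
            if r.taxid in out:
                raise ValidationError(f"duplicate TAXID {r.taxid} in community")
            out[r.taxid] = r
        return out


def _read_lines(src: PathOrBuffer) -> list[str]:
    if isinstance(src, (str, Path)):
        text = Path(src).read_text()
    else:
        text = src.read()
    return text.splitlines()


def species_from_clade(clade: str) -> str:
    """Extract the species name from a ranked clade string.

    ``k__Bacteria|...|g__Escherichia|s__Escherichia_coli`` yields
    ``Escherichia_coli`` (underscores kept; standardization is a separate,
    later step).
    """
    segments = clade.split("|")
    species = [s[len("s__"):] for s in segments if s.startswith("s__")]
    if not species:
        raise ProfileParseError(f"no s__ segment in clade string {clade!r}")
    return species[-1]


def parse_marker_profile(
    src: PathOrBuffer,
    version: int = 4,
    sample_id: str = "sample",
    pipeline_id: str = "marker",
) -> AbundanceProfile:
    """Parse a marker-gene taxonomic profile (ranked clade strings).

    Only species-level rows (carrying an ``s__`` segment) are kept.  For
    ``version=4`` outputs, rows that additionally carry a sub-species
    ``t__`` genome-bin segment are excluded so each species appears once.
    Marker-gene profilers do not report an unclassified fraction, so
    ``unclassified_pct`` is ``None``.
    """
    if version not in (3, 4):
        raise ValueError(f"unsupported marker profile version: {version}")
    records = []
    for lineno, line in enumerate(_read_lines(src), start=1):
        if not line.strip() or line.startswith("#") or "taxonomy" in line.split("\t")[0]:
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ProfileParseError(f"line {lineno}: expected clade<TAB>abundance")
        clade = parts[0]
        if "s__" not in clade:
            continue
        if version == 4 and "t__" in clade:
            continue
        try:
            abund = float(parts[1])
        except ValueError as exc:
            raise ProfileParseError(
                f"line {lineno}: non-numeric abundance {parts[1]!r}"
            ) from exc
        records.append(TaxonRecord(species_from_clade(clade), None, abund))
    if not records:
        warnings.warn("marker profile contained no species-level rows")
    return AbundanceProfile(sample_id, pipeline_id, records, None).validate()


def parse_count_report(
    src: PathOrBuffer,
    sample_id: str = "sample",
    pipeline_id: str = "kmer",
) -> AbundanceProfile:
    """Parse a k-mer classifier species report (name, TAXID, count rows).

    An optional leading ``Unclassified<TAB><pct>%`` line is captured as the
    profile's unclassified fraction.  Relative abundance of each species is
    ``100 * count / sum(counts)`` over classified species only.
    """
    lines = [l for l in _read_lines(src) if l.strip()]
    unclassified = None
    rows = []
    for lineno, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if parts[0].strip().lower() == "unclassified":
            value = parts[-1].strip().rstrip("%")
            unclassified = float(value)
            continue
        if len(parts) < 3:
            raise ProfileParseError(
                f"line {lineno}: expected name<TAB>taxid<TAB>count"
            )
        name, taxid_s, count_s = parts[0], parts[1], parts[2]
        try:
            taxid = int(taxid_s)
        except ValueError as exc:
            raise ProfileParseError(
                f"line {lineno}: non-integer TAXID {taxid_s!r}"
            ) from exc
        rows.append((name, taxid, float(count_s)))
    total = sum(c for _, _, c in rows)
    if total <= 0:
        raise DegenerateInputError("count report has zero total count")
    records = [TaxonRecord(n, t, 100.0 * c / total) for n, t, c in rows]
    # percentages are of the classified fraction; unclassified is carried
    # separately and never folded into the 100%
    profile = AbundanceProfile(sample_id, pipeline_id, records, unclassified)
    if unclassified is None:
        profile.validate()
    return profile


def parse_ogu_table(
    src: PathOrBuffer,
    sample_id: str = "sample",
    pipeline_id: str = "ogu",
) -> AbundanceProfile:
    """Parse an OGU classifier table: (TAXID, count, organism name) rows.

    TAXIDs ship in the file itself, so profiles from this dialect never
    need the name-resolution step.
    """
    rows = []
    for lineno, line in enumerate(_read_lines(src), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ProfileParseError(
                f"line {lineno}: expected taxid<TAB>count<TAB>name"
            )
        try:
            taxid = int(parts[0])
        except ValueError as exc:
            raise ProfileParseError(
                f"line {lineno}: non-integer TAXID {parts[0]!r}"
            ) from exc
        rows.append((taxid, float(parts[1]), parts[2]))
    total = sum(c for _, c, _ in rows)
    if total <= 0:
        raise DegenerateInputError("OGU table has zero total count")
    records = [TaxonRecord(n, t, 100.0 * c / total) for t, c, n in rows]
    return AbundanceProfile(sample_id, pipeline_id, records, None).validate()


def parse_long_table(
    src: PathOrBuffer,
    sample_id: Optional[str] = None,
    pipeline_id: str = "generic",
) -> AbundanceProfile:
    """Parse a generic long-format table with columns name, rel_abund
    [, taxid, sample_id, rank].

    A row named ``Unclassified`` moves to ``unclassified_pct``.  Rows whose
    ``rank`` column marks them as classified only above species level are
    likewise added into the unclassified fraction rather than kept as
    species records.
    """
    df = pd.read_csv(src, sep="\t", dtype={"name": str})
    missing = {"name", "rel_abund"} - set(df.columns)
    if missing:
        raise SchemaError(f"long table missing mandatory columns: {sorted(missing)}")
    if df.empty:
        warnings.warn("long table is empty")
        return AbundanceProfile(sample_id or "sample", pipeline_id, [], None)
    if sample_id is None:
        if "sample_id" in df.columns:
            ids = df["sample_id"].unique()
            if len(ids) > 1:
                raise SchemaError(
                    f"long table mixes samples {list(ids)}; pass sample_id"
                )
            sample_id = str(ids[0])
        else:
            sample_id = "sample"
    unclassified = 0.0
    has_unclassified = False
    records = []
    for _, row in df.iterrows():
        name = str(row["name"])
        abund = float(row["rel_abund"])
        if name.strip().lower() == "unclassified":
            unclassified += abund
            has_unclassified = True
            continue
        rank = str(row["rank"]) if "rank" in df.columns and pd.notna(row.get("rank")) else "species"
        if rank not in ("species", "strain"):
            # classified only at a higher rank: counts as unclassified
            unclassified += abund
            has_unclassified = True
            continue
        taxid = None
        if "taxid" in df.columns and pd.notna(row["taxid"]):
            taxid = int(row["taxid"])
        records.append(TaxonRecord(name, taxid, abund))
    return AbundanceProfile(
        sample_id,
        pipeline_id,
        records,
        unclassified if has_unclassified else None,
    ).validate()


def parse_profile(src: PathOrBuffer, dialect: str, **kwargs) -> AbundanceProfile:
    """Dispatch to the parser for a named dialect (no auto-detection)."""
    parsers = {
        "marker_profile": parse_marker_profile,
        "count_report": parse_count_report,
        "ogu_table": parse_ogu_table,
        "long_table": parse_long_table,
    }
    if dialect not in parsers:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    return parsers[dialect](src, **kwargs)


def read_expected(src: PathOrBuffer) -> dict[str, ExpectedComposition]:
    """Read expected (ground-truth) compositions from a long-format TSV.

    Columns: ``community_id``, ``name``, ``expected_pct`` and optionally
    ``taxid``.  Returns one validated composition per community.
    """
    df = pd.read_csv(src, sep="\t", dtype={"name": str, "community_id": str})
    missing = {"community_id", "name", "expected_pct"} - set(df.columns)
    if missing:
        raise SchemaError(f"expected table missing columns: {sorted(missing)}")
    out = {}
    for community, sub in df.groupby("community_id", sort=False):
        records = []
        for _, row in sub.iterrows():
            taxid = None
            if "taxid" in sub.columns and pd.notna(row["taxid"]):
                taxid = int(row["taxid"])
            if float(row["expected_pct"]) <= 0:
                raise ValidationError(
                    f"expected taxon {row['name']!r} in {community!r} "
                    f"listed at {row['expected_pct']}%"
                )
            records.append(TaxonRecord(str(row["name"]), taxid, float(row["expected_pct"])))
        out[str(community)] = ExpectedComposition(str(community), records).validate()
    return out


def write_expected(
    compositions: Union[ExpectedComposition, Sequence[ExpectedComposition]],
    path: Union[str, Path],
) -> None:
    """Write one or more expected compositions as a long-format TSV."""
    if isinstance(compositions, ExpectedComposition):
        compositions = [compositions]
    frames = []
    for comp in compositions:
        frame = comp.to_frame().rename(columns={"expected_pct": "expected_pct"})
        frame.insert(0, "community_id", comp.community_id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
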