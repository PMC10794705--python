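"""Organism-name standardization and TAXID resolution.

Profilers disagree about how they spell organism names: strain tags,
bracketed tentative genera, subspecies qualifiers and plain renames all
break naive string joins between pipelines.  The fix used here is to map
every name onto a canonical uppercase token string and resolve that
through an index built from NCBI taxonomy dump files, so each organism is
keyed by its stable numeric TAXID from then on.

Standardization rule (deterministic and idempotent):

* split the raw name on whitespace;
* first token is the genus: strip ``[`` and ``]`` (tentative-genus marks);
* every later token: replace characters outside letters, digits, ``.``
  and ``-`` with ``-`` (this keeps strain tags like ``LV10R510-8`` intact);
* join the tokens with ``_`` and uppercase the result.

``Marinobacter sp. LV10R510-8`` becomes ``MARINOBACTER_SP._LV10R510-8``;
single-word names such as ``Escherichia`` are only uppercased.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .exceptions import (
    DumpParseError,
    InvalidNameError,
    NameResolutionError,
    ValidationError,
)
from .profiles import AbundanceProfile, ExpectedComposition, TaxonRecord

logger = logging.getLogger(__name__)

_TOKEN_CLEAN = re.compile(r"[^A-Za-z0-9.\-]")

INDEX_FORMAT_TAG = "#taxabench-index"


def standardize_name(raw: str) -> str:
    """Standardize a free-form organism name to its canonical token string."""
    if raw is None or not str(raw).strip():
        raise InvalidNameError(f"empty or whitespace-only organism name: {raw!r}")
    tokens = str(raw).split()
    genus = tokens[0].replace("[", "").replace("]", "")
    rest = [_TOKEN_CLEAN.sub("-", t) for t in tokens[1:]]
    return "_".join([genus] + rest).upper()


def _split_dump_line(line: str):
    # taxdump dialect: fields separated by "\t|\t", record terminated "\t|"
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


class TaxonomyIndex:
    """Mapping from standardized organism names to TAXIDs.

    Collisions (two dump records standardizing to the same key) are
    resolved deterministically — scientific-name records win, then the
    lowest TAXID — and recorded in :attr:`collisions` for auditing.
    """

    def __init__(
        self,
        entries: Mapping[str, int],
        source_version: str = "unversioned",
        collisions: Optional[dict[str, list[int]]] = None,
    ):
        for name, taxid in entries.items():
            if taxid < 1:
                raise ValidationError(f"invalid TAXID {taxid} for {name!r}")
        self.entries: dict[str, int] = dict(entries)
        self.source_version = source_version
        self.collisions = dict(collisions or {})

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, standard_name: str) -> bool:
        return standard_name in self.entries

    def lookup(self, standard_name: str) -> Optional[int]:
        return self.entries.get(standard_name)

    def save(self, path: Union[str, Path]) -> None:
        """Persist as a versioned two-column TSV (diffable, byte-stable)."""
        lines = [f"{INDEX_FORMAT_TAG}\t{self.source_version}"]
        lines += [f"{name}\t{taxid}" for name, taxid in sorted(self.entries.items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TaxonomyIndex":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith(INDEX_FORMAT_TAG):
            raise ValidationError(f"{path}: not a taxabench index file")
        version = lines[0].split("\t", 1)[1] if "\t" in lines[0] else "unversioned"
        entries = {}
        for line in lines[1:]:
            if not line.strip():
                continue
            name, taxid = line.split("\t")
            entries[name] = int(taxid)
        return cls(entries, source_version=version)


def _parse_merged_dump(path: Union[str, Path]) -> dict[int, int]:
    remap = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dump_line(line)
        if len(fields) < 2:
            raise DumpParseError(path, lineno, "merged.dmp record needs 2 fields")
        remap[int(fields[0])] = int(fields[1])
    return remap


def build_taxonomy_index(
    names_dump: Union[str, Path],
    nodes_dump: Optional[Union[str, Path]] = None,
    merged_dump: Optional[Union[str, Path]] = None,
    source_version: str = "unversioned",
) -> TaxonomyIndex:
    """Build a standardized-name -> TAXID index from taxonomy dump files.

    Every name record in ``names_dump`` yields a candidate entry keyed by
    :func:`standardize_name`.  ``nodes_dump`` is accepted for completeness
    of the dump pair but ranks are not needed for flat name lookup.  If a
    ``merged_dump`` is supplied, retired TAXIDs are remapped to their
    current ids before indexing.
    """
    remap = _parse_merged_dump(merged_dump) if merged_dump else {}
    # candidates[key] = list of (is_scientific, taxid)
    candidates: dict[str, list[tuple[bool, int]]] = {}
    n_records = 0
    for lineno, line in enumerate(Path(names_dump).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dump_line(line)
        if len(fields) < 4:
            raise DumpParseError(
                names_dump, lineno, f"expected 4 pipe-delimited fields, got {len(fields)}"
            )
        try:
            taxid = int(fields[0])
        except ValueError as exc:
            raise DumpParseError(
                names_dump, lineno, f"non-integer tax_id {fields[0]!r}"
            ) from exc
        name_txt, name_class = fields[1], fields[3]
        taxid = remap.get(taxid, taxid)
        key = standardize_name(name_txt)
        candidates.setdefault(key, []).append(
            (name_class.strip() == "scientific name", taxid)
        )
        n_records += 1
    if n_records == 0:
        warnings.warn(f"names dump {names_dump} is empty; index has no entries")

    if nodes_dump is not None:
        # parsed only to validate the dump pair; rank info is not indexed
        for lineno, line in enumerate(Path(nodes_dump).read_text().splitlines(), start=1):
            if line.strip() and len(_split_dump_line(line)) < 3:
                raise DumpParseError(nodes_dump, lineno, "nodes.dmp record needs >=3 fields")

    entries: dict[str, int] = {}
    collisions: dict[str, list[int]] = {}
    for key, cands in candidates.items():
        taxids = sorted({t for _, t in cands})
        if len(taxids) > 1:
            scientific = sorted({t for sci, t in cands if sci})
            chosen = scientific[0] if scientific else taxids[0]
            collisions[key] = taxids
            logger.warning(
                "name collision for %r: TAXIDs %s, keeping %d", key, taxids, chosen
            )
        else:
            chosen = taxids[0]
        entries[key] = chosen
    return TaxonomyIndex(entries, source_version=source_version, collisions=collisions)


def annotate_taxids(
    names: Iterable[str], index: TaxonomyIndex
) -> dict[str, int]:
    """Resolve raw organism names to TAXIDs through the index.

    All names are attempted; if any fail, one aggregated
    :class:`NameResolutionError` lists every offending name.
    """
    if len(index) == 0:
        raise ValidationError("taxonomy index is empty")
    resolved: dict[str, int] = {}
    unresolved: list[str] = []
    for raw in names:
        taxid = index.lookup(standardize_name(raw))
        if taxid is None:
            unresolved.append(raw)
        else:
            resolved[raw] = taxid
    if unresolved:
        raise NameResolutionError(unresolved)
    return resolved


def annotate_profile(
    profile: AbundanceProfile, index: TaxonomyIndex
) -> AbundanceProfile:
    """Return a copy of ``profile`` with TAXIDs filled in from the index."""
    mapping = annotate_taxids([r.name for r in profile.records], index)
    return profile.with_records(
        TaxonRecord(r.name, mapping[r.name], r.rel_abund) for r in profile.records
    )


# ---------------------------------------------------------------------------
# curation rules

VALID_RULE_KINDS = ("rename", "merge", "reclassify")


@dataclass(frozen=True)
class CurationRule:
    """A name-level fix applied before/around TAXID resolution.

    ``rename``     — spelling or clade-name fix, abundance untouched.
    ``merge``      — fold a taxon into another, summing abundances.
    ``reclassify`` — move a sub-species/serotype entry to its species-level
                     name and TAXID.
    """

    kind: str
    from_name: str
    to_name: str
    to_taxid: Optional[int] = None

    def __post_init__(self):
        if self.kind not in VALID_RULE_KINDS:
            raise ValidationError(f"unknown curation kind {self.kind!r}")
        if self.kind == "reclassify" and self.to_taxid is None:
            raise ValidationError("reclassify rules must carry a target TAXID")


def load_curations(path: Optional[Union[str, Path]] = None) -> list[CurationRule]:
    """Load curation rules from a TSV (kind, from_name, to_name, to_taxid).

    With no path, the bundled default rule set is returned: the clade-A
    rename of Prevotella copri, the Clostridium clostridiiforme spelling
    fix, species-level reclassification of the Salmonella enterica
    subspecies and the E. coli O157:H7 serotype, and the merge of
    Bifidobacterium longum subsp. longum into its species.
    """
    if path is None:
        ref = resources.files("taxabench").joinpath("data/curations.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l.strip()]
    header = lines[0].split("\t")
    if header[:3] != ["kind", "from_name", "to_name"]:
        raise ValidationError("curation file must start with kind/from_name/to_name")
    rules = []
    for line in lines[1:]:
        parts = line.split("\t")
        taxid = int(parts[3]) if len(parts) > 3 and parts[3].strip() else None
        rules.append(CurationRule(parts[0], parts[1], parts[2], taxid))
    return rules


def apply_curations(
    profile: Union[AbundanceProfile, ExpectedComposition],
    rules: Iterable[CurationRule],
) -> Union[AbundanceProfile, ExpectedComposition]:
    """Apply curation rules to a profile; absent names are a no-op.

    Matching is done on standardized names so the same rule file covers
    space- and underscore-separated spellings.  Merges (and renames that
    land on an existing taxon) sum relative abundances; the total
    abundance is conserved exactly.
    """
    rule_map = {standardize_name(r.from_name): r for r in rules}
    new_records: list[TaxonRecord] = []
    touched: set[str] = set()
    for rec in profile.records:
        rule = rule_map.get(standardize_name(rec.name))
        if rule is None:
            new_records.append(rec)
            continue
        touched.add(standardize_name(rule.to_name))
        new_records.append(TaxonRecord(rule.to_name, rule.to_taxid or rec.taxid, rec.rel_abund))

    # sum any duplicates created by merges/renames
    merged: dict[str, TaxonRecord] = {}
    order: list[str] = []
    for rec in new_records:
        key = standardize_name(rec.name)
        if key in merged:
            if key not in touched:
                raise ValidationError(
                    f"duplicate taxon {rec.name!r} not produced by a curation rule"
                )
            prev = merged[key]
            merged[key] = TaxonRecord(
                prev.name, prev.taxid or rec.taxid, prev.rel_abund + rec.rel_abund
            )
        else:
            merged[key] = rec
            order.append(key)

    out_records = [merged[k] for k in order]
    if isinstance(profile, ExpectedComposition):
        return ExpectedComposition(profile.community_id, out_records)
    return profile.with_records(out_records)
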