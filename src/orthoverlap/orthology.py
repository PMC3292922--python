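"""Orthology maps and projection of screen hits onto the worm reference space.

Maps are consumed, never computed: the supported inputs are an OrthoMCL-style
groups file ("GROUP: sp|gene sp|gene ...") and a pairwise ortholog TSV. When
both are loaded their union is used; queries are deterministic and one-to-many
relations are fully expanded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError
from .id_normalization import (
    DEFAULT_OPTIONS,
    AliasTable,
    GeneId,
    NormalizationOptions,
    normalize_gene_id,
)
from .study_catalog import RawGeneCall, Study

logger = logging.getLogger(__name__)

#: Default prefix dialect for groups files.
DEFAULT_SPECIES_PREFIXES = {"cel": "worm", "sce": "yeast", "dme": "fly", "hsa": "human"}


@dataclass
class OrthologyMap:
    """A many-to-many cross-species gene relation as a set of groups."""

    groups: list[frozenset[GeneId]] = field(default_factory=list)
    _index: dict[tuple[str, str], set[int]] = field(default_factory=dict, repr=False)
    dialect: str = ""
    n_skipped_members: int = 0

    def add_group(self, members: frozenset[GeneId]) -> None:
        if not members:
            return
        idx = len(self.groups)
        self.groups.append(members)
        for gene in members:
            self._index.setdefault((gene.species, gene.value), set()).add(idx)

    def groups_of(self, gene: GeneId) -> list[frozenset[GeneId]]:
        return [self.groups[i] for i in sorted(self._index.get((gene.species, gene.value), ()))]

    def __contains__(self, gene: GeneId) -> bool:
        return (gene.species, gene.value) in self._index

    def __len__(self) -> int:
        return len(self.groups)

    def union(self, other: "OrthologyMap") -> "OrthologyMap":
        """Pool two maps; queries see the union of both relations."""
        merged = OrthologyMap(dialect=f"{self.dialect}+{other.dialect}")
        for grp in self.groups:
            merged.add_group(grp)
        for grp in other.groups:
            merged.add_group(grp)
        return merged

    def reference_universe(self) -> list[GeneId]:
        """All distinct worm genes reachable through the map, sorted."""
        worms = {g for grp in self.groups for g in grp if g.species == "worm"}
        return sorted(worms, key=lambda g: g.value)


@dataclass(frozen=True)
class MappedCall:
    """A raw hit after projection onto the worm gene space."""

    source: RawGeneCall
    source_gene: GeneId
    worm_orthologues: frozenset[GeneId]
    mapping_status: str  # direct | mapped | unmapped

    def __post_init__(self) -> None:
        if self.mapping_status not in ("direct", "mapped", "unmapped"):
            raise ValidationError(f"bad mapping_status {self.mapping_status!r}")


def read_orthomcl_groups(
    path,
    species_prefixes: dict[str, str] | None = None,
    aliases: AliasTable | None = None,
    options: NormalizationOptions = DEFAULT_OPTIONS,
) -> OrthologyMap:
    """Parse a groups file; unknown prefixes are skipped with a counted warning."""
    prefixes = dict(DEFAULT_SPECIES_PREFIXES if species_prefixes is None else species_prefixes)
    omap = OrthologyMap(dialect="orthomcl-groups")
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise FormatError(f"{path}: line {lineno}: malformed group line (no colon)")
            _, _, body = line.partition(":")
            members: set[GeneId] = set()
            for token in body.split():
                prefix, sep, value = token.partition("|")
                if not sep:
                    raise FormatError(
                        f"{path}: line {lineno}: member {token!r} lacks a species prefix"
                    )
                species = prefixes.get(prefix)
                if species is None:
                    omap.n_skipped_members += 1
                    logger.warning(
                        "%s line %d: unknown species prefix %r, member skipped",
                        path,
                        lineno,
                        prefix,
                    )
                    continue
                members.add(normalize_gene_id(value, species, aliases, options))
            if not members:
                logger.warning("%s line %d: empty group skipped", path, lineno)
                continue
            omap.add_group(frozenset(members))
    return omap


def read_pairwise_orthologs(
    path,
    aliases: AliasTable | None = None,
    options: NormalizationOptions = DEFAULT_OPTIONS,
) -> OrthologyMap:
    """Parse a pairwise ortholog TSV; each row becomes a two-member group."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"source_species", "source_id", "target_species", "target_id"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(
            f"pairwise ortholog table missing column(s): {', '.join(sorted(missing))}"
        )
    omap = OrthologyMap(dialect="pairwise")
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        if row.source_species == row.target_species:
            raise ValidationError(
                f"{path} row {i}: source and target species are both "
                f"{row.source_species!r}; paralogy rows are not accepted here"
            )
        src = normalize_gene_id(row.source_id, row.source_species, aliases, options)
        tgt = normalize_gene_id(row.target_id, row.target_species, aliases, options)
        omap.add_group(frozenset({src, tgt}))
    return omap


def worm_orthologues(gene: GeneId, omap: OrthologyMap) -> list[GeneId]:
    """All worm members of every group containing *gene*, in lexicographic order.

    A worm query returns itself (identity: this module never maps worm genes to
    worm paralogues); a gene absent from the map returns an empty list.
    """
    if gene.species == "worm":
        return [gene]
    worms = {
        member
        for grp in omap.groups_of(gene)
        for member in grp
        if member.species == "worm"
    }
    return sorted(worms, key=lambda g: g.value)


def map_study(
    study: Study,
    calls: list[RawGeneCall],
    omap: OrthologyMap,
    aliases: AliasTable | None = None,
    options: NormalizationOptions = DEFAULT_OPTIONS,
) -> tuple[list[MappedCall], int]:
    """Project every raw call of one study; returns (mapped calls, distinct worm count)."""
    mapped: list[MappedCall] = []
    distinct: set[GeneId] = set()
    for call in calls:
        if call.study_id != study.study_id:
            raise ValidationError(
                f"call {call.raw_id!r} belongs to study {call.study_id}, not {study.study_id}"
            )
        source_gene = normalize_gene_id(call.raw_id, call.species, aliases, options)
        if source_gene.species == "worm":
            worms = [source_gene]
            status = "direct"
        else:
            worms = worm_orthologues(source_gene, omap)
            status = "mapped" if worms else "unmapped"
        mapped.append(
            MappedCall(
                source=call,
                source_gene=source_gene,
                worm_orthologues=frozenset(worms),
                mapping_status=status,
            )
        )
        distinct.update(worms)
    return mapped, len(distinct)
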