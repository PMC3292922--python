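"""Reference-space regulator catalog and cross-study overlap detection.

Every mapped hit contributes evidence records (study, source gene, effect) to
its worm gene(s). The overlap unit is the worm gene; paralogue groups sharing
identical non-worm source evidence are merged only afterwards, keeping the set
algebra simple and the grouping auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import ValidationError
from .id_normalization import GeneId
from .orthology import MappedCall
from .study_catalog import Study

#: evidence record: (study_id, source gene, effect)
Evidence = tuple[str, GeneId, str]


@dataclass
class RegulatorEntry:
    """One worm gene with all per-study evidence behind it."""

    gene: GeneId
    evidence: set[Evidence] = field(default_factory=set)
    studies: set[str] = field(default_factory=set)
    organisms: set[str] = field(default_factory=set)
    disease_models: set[str] = field(default_factory=set)

    @property
    def n_studies(self) -> int:
        return len(self.studies)


@dataclass
class RegulatorCatalog:
    """Deduplicated reference-space union of all mapped hits."""

    entries: dict[GeneId, RegulatorEntry] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_evidence(self) -> int:
        return sum(len(e.evidence) for e in self.entries.values())


@dataclass(frozen=True)
class OverlapEntry:
    """A worm gene (or paralogue group) identified in >= 2 studies."""

    genes: frozenset[GeneId]
    studies: frozenset[str]
    organisms: frozenset[str]
    disease_models: frozenset[str]
    evidence: frozenset[Evidence] = frozenset()
    display_names: tuple[str, ...] = ()
    description: str = ""
    human_orthologues: frozenset[str] = frozenset()
    neuronal_expression: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("an overlap entry must contain at least one gene")

    @property
    def sequence_names(self) -> tuple[str, ...]:
        return tuple(sorted(g.value for g in self.genes))


def integrate_catalog(
    studies: list[Study],
    mapped: dict[str, list[MappedCall]],
) -> RegulatorCatalog:
    """Union all studies' mapped calls into one entry per distinct worm gene."""
    by_id = {s.study_id: s for s in studies}
    unknown = set(mapped) - set(by_id)
    if unknown:
        raise ValidationError(f"mapped calls reference unknown studies: {sorted(unknown)}")
    catalog = RegulatorCatalog()
    n_unmapped = 0
    for study_id in sorted(mapped):
        study = by_id[study_id]
        for call in mapped[study_id]:
            if call.mapping_status == "unmapped":
                n_unmapped += 1
                continue
            for worm_gene in call.worm_orthologues:
                entry = catalog.entries.get(worm_gene)
                if entry is None:
                    entry = RegulatorEntry(gene=worm_gene)
                    catalog.entries[worm_gene] = entry
                entry.evidence.add((study_id, call.source_gene, call.source.effect))
                entry.studies.add(study_id)
                entry.organisms.add(study.organism)
                entry.disease_models.update(study.disease_models)
    catalog.provenance = {
        "n_studies": len(studies),
        "n_raw_calls": sum(len(v) for v in mapped.values()),
        "n_unmapped_calls": n_unmapped,
        "n_entries": len(catalog),
    }
    return catalog


def find_overlaps(catalog: RegulatorCatalog, min_studies: int = 2) -> list[OverlapEntry]:
    """Entries present in >= min_studies distinct studies, one per worm gene.

    Sorted by (-n_studies, gene value) for byte-stable output.
    """
    if min_studies < 2:
        raise ValidationError(f"min_studies must be >= 2, got {min_studies}")
    hits = [e for e in catalog.entries.values() if len(e.studies) >= min_studies]
    hits.sort(key=lambda e: (-len(e.studies), e.gene.value))
    out = []
    for e in hits:
        names = tuple([e.gene.display_name] if e.gene.display_name else [])
        out.append(
            OverlapEntry(
                genes=frozenset({e.gene}),
                studies=frozenset(e.studies),
                organisms=frozenset(e.organisms),
                disease_models=frozenset(e.disease_models),
                evidence=frozenset(e.evidence),
                display_names=names,
            )
        )
    return out


def _merge_signature(entry: OverlapEntry) -> frozenset | None:
    """Grouping key: the full evidence set, provided every source gene is non-worm."""
    if any(src.species == "worm" for _, src, _ in entry.evidence):
        return None
    if not entry.evidence:
        return None
    return frozenset((sid, src.species, src.value, eff) for sid, src, eff in entry.evidence)


def group_paralogue_entries(
    overlaps: list[OverlapEntry], catalog: RegulatorCatalog | None = None
) -> list[OverlapEntry]:
    """Merge overlap entries whose worm genes share an identical non-worm evidence set.

    Joint orthologues of one source gene (a planted or real paralogue group,
    e.g. two worm 14-3-3 genes hit only through one fly gene) collapse into a
    single multi-gene entry; everything else passes through unchanged.
    """
    by_sig: dict[frozenset, list[OverlapEntry]] = {}
    order: list[tuple[frozenset | None, OverlapEntry]] = []
    for entry in overlaps:
        sig = _merge_signature(entry)
        if sig is not None:
            by_sig.setdefault(sig, []).append(entry)
        order.append((sig, entry))

    emitted: set[frozenset] = set()
    merged: list[OverlapEntry] = []
    for sig, entry in order:
        if sig is None or len(by_sig[sig]) == 1:
            merged.append(entry)
            continue
        if sig in emitted:
            continue
        emitted.add(sig)
        bucket = by_sig[sig]
        merged.append(
            OverlapEntry(
                genes=frozenset().union(*(e.genes for e in bucket)),
                studies=frozenset().union(*(e.studies for e in bucket)),
                organisms=frozenset().union(*(e.organisms for e in bucket)),
                disease_models=frozenset().union(*(e.disease_models for e in bucket)),
                evidence=entry.evidence,
                display_names=tuple(n for e in bucket for n in e.display_names),
                description=entry.description,
            )
        )
    return merged


_OVERLAP_COLUMNS = (
    "sequence_names",
    "gene_names",
    "description",
    "organisms",
    "disease_models",
    "neuronal_expression",
    "studies",
    "human_orthologues",
)


def write_overlap_table(overlaps: list[OverlapEntry], path) -> None:
    """Render overlap entries to a deterministic TSV."""
    rows = []
    for e in overlaps:
        rows.append(
            {
                "sequence_names": ", ".join(e.sequence_names),
                "gene_names": ", ".join(e.display_names) if e.display_names else "-",
                "description": e.description,
                "organisms": ", ".join(sorted(e.organisms)),
                "disease_models": ", ".join(sorted(e.disease_models)),
                "neuronal_expression": e.neuronal_expression,
                "studies": ", ".join(sorted(e.studies)),
                "human_orthologues": ", ".join(sorted(e.human_orthologues)),
            }
        )
    pd.DataFrame(rows, columns=list(_OVERLAP_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_overlap_table(path) -> list[OverlapEntry]:
    """Re-read a written overlap TSV (round-trips gene/study/annotation sets)."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)

    def _split(cell: str) -> list[str]:
        return [t for part in cell.split(",") if (t := part.strip())]

    out = []
    for row in frame.itertuples(index=False):
        genes = frozenset(GeneId("worm", v) for v in _split(row.sequence_names))
        names = tuple(n for n in _split(row.gene_names) if n != "-")
        out.append(
            OverlapEntry(
                genes=genes,
                studies=frozenset(_split(getattr(row, "studies", ""))),
                organisms=frozenset(_split(row.organisms)),
                disease_models=frozenset(_split(row.disease_models)),
                display_names=names,
                description=row.description,
                human_orthologues=frozenset(_split(getattr(row, "human_orthologues", ""))),
                neuronal_expression=row.neuronal_expression,
            )
        )
    return out


def write_catalog_table(catalog: RegulatorCatalog, path) -> None:
    """Flat per-gene catalog TSV (gene, display_name, studies, organisms, models, n_studies)."""
    rows = []
    for gene in sorted(catalog.entries, key=lambda g: g.value):
        e = catalog.entries[gene]
        rows.append(
            {
                "gene": gene.value,
                "display_name": gene.display_name or "",
                "studies": ", ".join(sorted(e.studies)),
                "organisms": ", ".join(sorted(e.organisms)),
                "disease_models": ", ".join(sorted(e.disease_models)),
                "n_studies": len(e.studies),
            }
        )
    pd.DataFrame(
        rows,
        columns=["gene", "display_name", "studies", "organisms", "disease_models", "n_studies"],
    ).to_csv(path, sep="\t", index=False)


def with_annotations(entry: OverlapEntry, **updates) -> OverlapEntry:
    """Functional update helper for annotation passes."""
    return replace(entry, **updates)
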