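"""Packaged curated fixtures: study catalog, overlap table, functional classes,
interaction edges, orthology groups, aliases and expression flags.

Fixtures are plain TSV/text data files with per-row provenance columns, so
transcription corrections never require code changes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotation_network import (
    FunctionalAnnotation,
    build_ppi_graph,
    load_annotations,
    load_expression_table,
)
from .errors import ValidationError
from .id_normalization import AliasTable, load_alias_table, normalize_gene_id
from .integration import OverlapEntry
from .orthology import OrthologyMap, read_orthomcl_groups
from .study_catalog import Study, parse_disease_models, read_study_table

_FILES = {
    "table1_catalog": "studies.tsv",
    "table2_overlaps": "table2_overlaps.tsv",
    "table3_classes": "table3_classes.tsv",
    "fig3_edges": "fig3_edges.tsv",
    "fig3_nodes": "fig3_nodes.tsv",
    "orthology_groups": "orthology_groups.txt",
    "aliases": "aliases.tsv",
    "expression": "expression.tsv",
    "vocabulary": "vocabulary.txt",
}

_ORGANISM_SPELLINGS = {"worm": "worm", "fly": "fly", "yeast": "yeast"}


def fixture_path(name: str):
    """Filesystem path of a packaged fixture file."""
    if name not in _FILES:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(_FILES))}"
        )
    return resources.files("orthoverlap").joinpath("data", _FILES[name])


def load_reference_aliases() -> AliasTable:
    return load_alias_table(fixture_path("aliases"))


def load_reference_orthology() -> OrthologyMap:
    """The curated orthology groups (worm/yeast/fly/human) for the overlap set."""
    return read_orthomcl_groups(fixture_path("orthology_groups"))


def _load_table2_overlaps() -> list[OverlapEntry]:
    """Expand the curated overlap table into one entry per worm gene.

    Rows listing several comma-separated sequence names yield one entry per
    gene, all sharing the row's source-gene evidence, so that paralogue
    grouping can reconstruct the printed row afterwards.
    """
    aliases = load_reference_aliases()
    frame = pd.read_csv(
        fixture_path("table2_overlaps"),
        sep="\t",
        comment="#",
        dtype=str,
        keep_default_na=False,
    )
    entries: list[OverlapEntry] = []
    for row in frame.itertuples(index=False):
        seq_names = [t.strip() for t in row.sequence_names.split(",") if t.strip()]
        gene_names = [t.strip() for t in row.gene_names.split(",") if t.strip() and t != "-"]
        organisms = frozenset(
            _ORGANISM_SPELLINGS[t.strip().casefold()]
            for t in row.organisms.split(",")
            if t.strip()
        )
        models = parse_disease_models(row.disease_models)
        evidence = []
        for token in row.source_genes.split(";"):
            token = token.strip()
            if not token:
                continue
            species, _, value = token.partition(":")
            evidence.append(("", normalize_gene_id(value, species), "unknown"))
        for i, seq in enumerate(seq_names):
            gene = normalize_gene_id(seq, "worm", aliases)
            display = gene_names[i] if i < len(gene_names) else (
                gene_names[0] if len(gene_names) == 1 else None
            )
            entries.append(
                OverlapEntry(
                    genes=frozenset({gene}),
                    studies=frozenset(),
                    organisms=organisms,
                    disease_models=models,
                    evidence=frozenset(evidence),
                    display_names=tuple([display]) if display else (),
                    description=row.description,
                    neuronal_expression=row.neuronal_expression,
                )
            )
    return entries


def load_fixture(name: str):
    """Load a packaged fixture as its typed, validated object.

    table1_catalog -> list[Study]; table2_overlaps -> list[OverlapEntry] (one
    per worm gene, pre-grouping); table3_classes -> list[FunctionalAnnotation];
    fig3_edges -> networkx.Graph.
    """
    if name == "table1_catalog":
        return read_study_table(fixture_path("table1_catalog"))
    if name == "table2_overlaps":
        return _load_table2_overlaps()
    if name == "table3_classes":
        return load_annotations(
            fixture_path("table3_classes"),
            fixture_path("vocabulary"),
            load_reference_aliases(),
        )
    if name == "fig3_edges":
        return build_ppi_graph(
            fixture_path("fig3_edges"), nodes_path=fixture_path("fig3_nodes")
        )
    raise ValidationError(
        "unknown fixture "
        f"{name!r}; available: table1_catalog, table2_overlaps, table3_classes, fig3_edges"
    )


def load_reference_expression() -> dict[str, str]:
    return load_expression_table(fixture_path("expression"))


__all__ = [
    "Study",
    "FunctionalAnnotation",
    "fixture_path",
    "load_fixture",
    "load_reference_aliases",
    "load_reference_orthology",
    "load_reference_expression",
]
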