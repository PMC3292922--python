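"""Functional classes, human orthologues, expression flags and the PPI subnetwork.

Annotations are controlled-vocabulary TSVs; the interaction network is a simple
graph over human protein labels with worm cross-references, interrogated via
connected components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import FormatError, ValidationError
from .id_normalization import AliasTable, GeneId, normalize_gene_id
from .integration import OverlapEntry, RegulatorCatalog, with_annotations
from .orthology import OrthologyMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FunctionalAnnotation:
    gene: GeneId
    functional_class: str
    source: str = ""


def load_vocabulary(path) -> list[str]:
    """Read the allowed functional classes, one per line, '#' comments ignored."""
    classes: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                classes.append(line)
    return classes


def load_annotations(
    path, vocabulary_path, aliases: AliasTable | None = None
) -> list[FunctionalAnnotation]:
    """Read gene/class annotations, hard-failing on classes outside the vocabulary."""
    vocabulary = set(load_vocabulary(vocabulary_path))
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = {"gene", "functional_class"} - set(frame.columns)
    if missing:
        raise FormatError(f"annotation table missing column(s): {', '.join(sorted(missing))}")
    out = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        if row.functional_class not in vocabulary:
            raise ValidationError(
                f"annotation row {i}: class {row.functional_class!r} not in vocabulary"
            )
        gene = normalize_gene_id(row.gene, "worm", aliases)
        out.append(
            FunctionalAnnotation(
                gene=gene,
                functional_class=row.functional_class,
                source=getattr(row, "source", ""),
            )
        )
    return out


def build_functional_matrix(
    catalog: RegulatorCatalog,
    annotations: list[FunctionalAnnotation],
    vocabulary: list[str] | None = None,
) -> pd.DataFrame:
    """Boolean study x class incidence: a cell is true iff some evidence record
    links the study to a gene annotated with the class."""
    class_of: dict[GeneId, set[str]] = {}
    for ann in annotations:
        class_of.setdefault(ann.gene, set()).add(ann.functional_class)

    studies = sorted({sid for e in catalog.entries.values() for sid in e.studies})
    columns = list(vocabulary) if vocabulary is not None else sorted(
        {ann.functional_class for ann in annotations}
    )
    matrix = pd.DataFrame(False, index=studies, columns=columns)
    for gene, entry in catalog.entries.items():
        for cls in class_of.get(gene, ()):
            if cls in matrix.columns:
                matrix.loc[sorted(entry.studies), cls] = True
    matrix.index.name = "study_id"
    return matrix


def attach_human_orthologues(
    overlaps: list[OverlapEntry], omap: OrthologyMap
) -> tuple[list[OverlapEntry], bool]:
    """Decorate each entry with human orthologue labels found through the map.

    Returns (annotated entries, all_covered) where all_covered reports whether
    every entry gained at least one human orthologue.
    """
    annotated = []
    all_covered = True
    for entry in overlaps:
        humans = {
            member.value
            for gene in entry.genes
            for grp in omap.groups_of(gene)
            for member in grp
            if member.species == "human"
        }
        if not humans:
            all_covered = False
        annotated.append(with_annotations(entry, human_orthologues=frozenset(humans)))
    return annotated, all_covered


_EXPRESSION_SPELLINGS = {
    "yes": "yes",
    "no": "no",
    "no?": "no",
    "?": "unknown",
    "unknown": "unknown",
    "": "unknown",
}


def load_expression_table(path) -> dict[str, str]:
    """Read worm gene -> neuronal-expression flags, normalized to {yes, no, unknown}."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = {"gene", "neuronal_expression"} - set(frame.columns)
    if missing:
        raise FormatError(f"expression table missing column(s): {', '.join(sorted(missing))}")
    table: dict[str, str] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        value = _EXPRESSION_SPELLINGS.get(row.neuronal_expression.strip().casefold())
        if value is None:
            raise ValidationError(
                f"expression row {i}: value {row.neuronal_expression!r} is not one of yes/no/unknown"
            )
        table[row.gene.strip()] = value
    return table


def attach_expression(
    overlaps: list[OverlapEntry], expression: dict[str, str]
) -> list[OverlapEntry]:
    """Flag each entry with neuronal expression; genes absent from the table are unknown.

    A multi-gene entry is 'yes' if any member is expressed, 'no' if any member
    is flagged no and none yes, else 'unknown'.
    """
    for value in expression.values():
        if value not in ("yes", "no", "unknown"):
            raise ValidationError(f"expression value {value!r} outside {{yes, no, unknown}}")
    annotated = []
    for entry in overlaps:
        flags = {expression.get(g.value, "unknown") for g in entry.genes}
        if "yes" in flags:
            flag = "yes"
        elif "no" in flags:
            flag = "no"
        else:
            flag = "unknown"
        annotated.append(with_annotations(entry, neuronal_expression=flag))
    return annotated


def build_ppi_graph(
    edges_path,
    restrict_to: set[str] | None = None,
    nodes_path=None,
) -> nx.Graph:
    """Build a simple interaction graph from a (protein_a, protein_b, provenance) TSV.

    Self-loop rows are skipped with a warning; duplicate rows collapse to one
    edge. With *restrict_to*, only edges with both endpoints inside the set are
    kept (plus the restricted nodes themselves). An optional nodes TSV attaches
    worm cross-references as node attributes.
    """
    frame = pd.read_csv(edges_path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = {"protein_a", "protein_b"} - set(frame.columns)
    if missing:
        raise FormatError(f"edge table missing column(s): {', '.join(sorted(missing))}")
    graph = nx.Graph()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        a, b = row.protein_a.strip(), row.protein_b.strip()
        if a == b:
            logger.warning("edge row %d: self-loop %s-%s skipped", i, a, b)
            continue
        if restrict_to is not None and (a not in restrict_to or b not in restrict_to):
            continue
        graph.add_edge(a, b, provenance=getattr(row, "provenance", ""))
    if restrict_to is not None:
        graph.add_nodes_from(restrict_to)
    if nodes_path is not None:
        nodes = pd.read_csv(nodes_path, sep="\t", comment="#", dtype=str, keep_default_na=False)
        for row in nodes.itertuples(index=False):
            label = row.protein.strip()
            if restrict_to is not None and label not in restrict_to:
                continue
            graph.add_node(
                label,
                worm_gene=getattr(row, "worm_gene", ""),
                worm_name=getattr(row, "worm_name", ""),
            )
    return graph


def connected_component(graph: nx.Graph, seed_node: str) -> list[str]:
    """Maximal connected node set containing *seed_node*, lexicographically ordered."""
    if seed_node not in graph:
        raise ValidationError(f"seed node {seed_node!r} not in graph")
    return sorted(nx.node_connected_component(graph, seed_node))
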