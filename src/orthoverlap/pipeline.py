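"""End-to-end driver: catalog -> normalization -> projection -> integration ->
annotation (-> overlap statistics when enabled), with a JSON stage summary."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotation_network import (
    attach_expression,
    attach_human_orthologues,
    build_functional_matrix,
    load_annotations,
    load_expression_table,
    load_vocabulary,
)
from .errors import OrthoverlapError
from .id_normalization import AliasTable, load_alias_table
from .integration import (
    find_overlaps,
    group_paralogue_entries,
    integrate_catalog,
    write_catalog_table,
    write_overlap_table,
)
from .orthology import OrthologyMap, map_study, read_orthomcl_groups, read_pairwise_orthologs
from .overlap_statistics import (
    DEFAULT_SEED,
    NullModelConfig,
    default_universe_size,
    overlap_report,
)
from .study_catalog import read_gene_list, read_study_table, summarize_catalog

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and switches for one pipeline run."""

    studies_path: str
    out_dir: str
    genes_dir: str | None = None
    groups_path: str | None = None
    pairwise_path: str | None = None
    aliases_path: str | None = None
    annotations_path: str | None = None
    vocabulary_path: str | None = None
    expression_path: str | None = None
    min_studies: int = 2
    group_paralogues: bool = True
    run_stats: bool = False
    universe_size: int | None = None
    n_perm: int = 10_000
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        for label, path in (
            ("studies", self.studies_path),
            ("genes-dir", self.genes_dir),
            ("groups", self.groups_path),
            ("pairwise", self.pairwise_path),
            ("aliases", self.aliases_path),
            ("annotations", self.annotations_path),
            ("vocabulary", self.vocabulary_path),
            ("expression", self.expression_path),
        ):
            if path is not None and not Path(path).exists():
                raise OrthoverlapError(f"{label} path does not exist: {path}")


@dataclass
class RunResult:
    summary: dict
    catalog: object
    overlaps: list
    stats: object | None = None
    functional_matrix: object | None = None


def run_full_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage in order, writing all artifacts under out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    studies = read_study_table(config.studies_path)
    catalog_summary = summarize_catalog(studies)

    aliases: AliasTable | None = None
    if config.aliases_path:
        aliases = load_alias_table(config.aliases_path)

    omap = OrthologyMap(dialect="empty")
    if config.groups_path:
        omap = read_orthomcl_groups(config.groups_path, aliases=aliases)
    if config.pairwise_path:
        pairwise = read_pairwise_orthologs(config.pairwise_path, aliases=aliases)
        omap = omap.union(pairwise) if len(omap) else pairwise

    mapped = {}
    per_study_distinct = {}
    n_raw = n_skipped = n_unmapped = 0
    if config.genes_dir:
        genes_dir = Path(config.genes_dir)
        for study in studies:
            path = genes_dir / f"{study.study_id}.tsv"
            if not path.exists():
                continue
            calls, skipped = read_gene_list(path, study)
            n_raw += len(calls)
            n_skipped += skipped
            study_mapped, distinct = map_study(study, calls, omap, aliases)
            n_unmapped += sum(1 for m in study_mapped if m.mapping_status == "unmapped")
            mapped[study.study_id] = study_mapped
            per_study_distinct[study.study_id] = distinct

    catalog = integrate_catalog(studies, mapped)
    overlaps = find_overlaps(catalog, min_studies=config.min_studies)
    n_pre_grouping = len(overlaps)
    if config.group_paralogues:
        overlaps = group_paralogue_entries(overlaps, catalog)

    all_have_human = None
    if len(omap):
        overlaps, all_have_human = attach_human_orthologues(overlaps, omap)

    functional_matrix = None
    if config.annotations_path and config.vocabulary_path:
        annotations = load_annotations(
            config.annotations_path, config.vocabulary_path, aliases
        )
        functional_matrix = build_functional_matrix(
            catalog, annotations, load_vocabulary(config.vocabulary_path)
        )
        functional_matrix.to_csv(out / "functional_matrix.tsv", sep="\t")

    if config.expression_path:
        overlaps = attach_expression(overlaps, load_expression_table(config.expression_path))

    stats = None
    if config.run_stats and per_study_distinct:
        universe = config.universe_size or default_universe_size(omap) or len(catalog)
        sizes = tuple(s for s in per_study_distinct.values() if s > 0)
        if universe and sizes and max(sizes) <= universe:
            null_config = NullModelConfig(
                universe_size=universe,
                study_sizes=sizes,
                n_perm=config.n_perm,
                seed=config.seed,
            )
            stats = overlap_report(catalog, overlaps, null_config, out / "stats.json")
        else:
            logger.warning("stats skipped: universe %s incompatible with sizes", universe)

    write_catalog_table(catalog, out / "catalog.tsv")
    write_overlap_table(overlaps, out / "overlaps.tsv")

    summary = {
        "n_studies": catalog_summary.n_studies,
        "total_reported": catalog_summary.total_reported,
        "total_orthologues_expected": catalog_summary.total_orthologues_expected,
        "n_raw_calls": n_raw,
        "n_skipped_rows": n_skipped,
        "n_unmapped_calls": n_unmapped,
        "n_distinct_genes": len(catalog),
        "per_study_distinct": per_study_distinct,
        "n_overlaps_pre_grouping": n_pre_grouping,
        "n_overlaps": len(overlaps),
        "all_overlaps_have_human_orthologue": all_have_human,
        "min_studies": config.min_studies,
        "group_paralogues": config.group_paralogues,
    }
    if stats is not None:
        summary["stats"] = {
            "observed": stats.observed,
            "p_value": stats.p_value,
            "mean_null": stats.mean_null,
            "expectation_closed_form": stats.expectation_closed_form,
        }
    with open(out / "summary.json", "w", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return RunResult(
        summary=summary,
        catalog=catalog,
        overlaps=overlaps,
        stats=stats,
        functional_matrix=functional_matrix,
    )
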