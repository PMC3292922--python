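"""Ground-truthed synthetic input bundles for end-to-end pipeline testing.

The generator emits the exact file shapes the pipeline consumes (studies.tsv,
genes/<study>.tsv, groups.txt, aliases.tsv, annotations.tsv, vocabulary.txt,
ppi_edges.tsv) together with a truth manifest recording the planted structure:
shared regulators forced into >= 2 studies, the full source -> reference map,
per-study distinct counts, paralogue pairs and class incidence. Only the data
shapes are simulated, not screen biology.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError

_WORM_PREFIXES = ("C", "F", "K", "T", "Y", "ZK", "R", "B")
_YEAST_LETTERS = "ABCDEFGHIJKLMNOP"

DISEASE_CODES = ("P", "S", "T", "SOD", "Abeta")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for one synthetic bundle; all fractions live in [0, 1]."""

    n_studies: dict = field(
        default_factory=lambda: {"worm": 2, "yeast": 2, "fly": 2}
    )
    universe_sizes: dict = field(
        default_factory=lambda: {"worm": 200, "yeast": 120, "fly": 120}
    )
    hits_range: tuple[int, int] = (8, 15)
    orthology_coverage: float = 1.0
    one_to_many_rate: float = 0.0
    n_planted_shared: int = 5
    planted_multiplicity: tuple[int, int] = (2, 3)
    paralogue_pair_rate: float = 0.0
    n_annotation_classes: int = 4
    disjoint_background: bool = True
    isoform_suffix_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("orthology_coverage", "one_to_many_rate", "paralogue_pair_rate",
                     "isoform_suffix_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.hits_range[0] < 1 or self.hits_range[0] > self.hits_range[1]:
            raise ValidationError(f"bad hits_range {self.hits_range}")
        if self.planted_multiplicity[0] < 2:
            raise ValidationError("planted_multiplicity must start at >= 2 studies")
        if self.n_planted_shared < 0:
            raise ValidationError("n_planted_shared must be >= 0")
        if sum(self.n_studies.values()) < self.planted_multiplicity[0] and self.n_planted_shared:
            raise ValidationError("not enough studies for the requested planting multiplicity")


@dataclass
class GroundTruth:
    """Planted structure recorded at generation time."""

    run_id: str
    planted_shared: dict  # worm gene -> sorted list of study_ids
    paralogue_groups: list  # list of sorted worm-gene lists sharing one source
    source_map: dict  # "species:gene" -> sorted list of worm genes
    study_sizes: dict  # study_id -> number of hit rows
    per_study_distinct: dict  # study_id -> distinct worm genes reachable
    distinct_reference_genes: int
    class_incidence: dict  # study_id -> sorted list of classes with a planted gene
    config: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json_file(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as handle:
            return cls(**json.load(handle))


def _worm_universe(n: int) -> list[str]:
    return [f"{_WORM_PREFIXES[i % len(_WORM_PREFIXES)]}{i:04d}.{1 + i % 4}" for i in range(n)]


def _fly_universe(n: int) -> list[str]:
    return [f"CG{10000 + i}" for i in range(n)]


def _yeast_universe(n: int) -> list[str]:
    return [f"Y{_YEAST_LETTERS[i % 16]}L{i:03d}W" for i in range(n)]


def _make_universes(config: SyntheticConfig) -> dict[str, list[str]]:
    makers = {"worm": _worm_universe, "fly": _fly_universe, "yeast": _yeast_universe}
    return {sp: makers[sp](config.universe_sizes.get(sp, 0)) for sp in ("worm", "yeast", "fly")}


def generate_synthetic_dataset(config: SyntheticConfig, out_dir) -> GroundTruth:
    """Write a complete input bundle under *out_dir* and return its ground truth.

    Deterministic for a fixed config (the seed lives inside the config); an
    infeasible planting request fails before any file is touched.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    universes = _make_universes(config)

    # --- studies and their sizes -------------------------------------------------
    study_ids: list[str] = []
    organism_of: dict[str, str] = {}
    for organism in ("worm", "yeast", "fly"):
        for _ in range(int(config.n_studies.get(organism, 0))):
            sid = f"s{len(study_ids) + 1:02d}"
            study_ids.append(sid)
            organism_of[sid] = organism
    if not study_ids:
        raise ValidationError("config declares no studies")
    lo, hi = config.hits_range
    sizes = {sid: int(rng.integers(lo, hi + 1)) for sid in study_ids}

    # --- plant shared regulators -------------------------------------------------
    worm_pool = list(universes["worm"])
    if config.n_planted_shared > len(worm_pool):
        raise ValidationError("more planted genes than the worm universe holds")
    planted_order = rng.permutation(len(worm_pool))
    planted = [worm_pool[i] for i in planted_order[: config.n_planted_shared]]
    background_pool = [worm_pool[i] for i in planted_order[config.n_planted_shared:]]

    n_pairs = int(round(config.paralogue_pair_rate * config.n_planted_shared))
    pair_partners: dict[str, str] = {}
    paralogue_groups: list[list[str]] = []

    capacity = dict(sizes)
    planted_membership: dict[str, list[str]] = {}
    mlo, mhi = config.planted_multiplicity
    nonworm_studies = [s for s in study_ids if organism_of[s] != "worm"]
    for k, gene in enumerate(planted):
        m = int(rng.integers(mlo, mhi + 1))
        if k < n_pairs:
            # paralogue pairs must arrive through a single non-worm source gene,
            # so their studies are drawn from one non-worm organism only
            orgs = sorted({organism_of[s] for s in nonworm_studies})
            orgs = [o for o in orgs if sum(1 for s in nonworm_studies if organism_of[s] == o) >= 2]
            if not orgs:
                raise ValidationError(
                    "paralogue planting needs >= 2 studies of one non-worm organism"
                )
            org = orgs[int(rng.integers(len(orgs)))]
            eligible = [s for s in study_ids if organism_of[s] == org and capacity[s] > 0]
        else:
            eligible = [s for s in study_ids if capacity[s] > 0]
        m = min(m, len(eligible))
        if m < 2:
            raise ValidationError(
                f"infeasible planting: gene {gene} cannot be placed in >= 2 studies"
            )
        chosen = [eligible[i] for i in rng.choice(len(eligible), size=m, replace=False)]
        for sid in chosen:
            capacity[sid] -= 1
        planted_membership[gene] = sorted(chosen)
        if k < n_pairs:
            if not background_pool:
                raise ValidationError("worm universe too small for paralogue partners")
            partner = background_pool.pop(0)
            pair_partners[gene] = partner
            paralogue_groups.append(sorted([gene, partner]))

    # --- orthology map: planted sources first, then covered background ------------
    source_map: dict[str, list[str]] = {}
    used_sources = {"yeast": 0, "fly": 0}

    def _next_source(organism: str) -> str:
        pool = universes[organism]
        if used_sources[organism] >= len(pool):
            raise ValidationError(f"{organism} universe too small for required sources")
        gene = pool[used_sources[organism]]
        used_sources[organism] += 1
        return gene

    planted_source: dict[tuple[str, str], str] = {}
    for gene in planted:
        targets = sorted({gene} | ({pair_partners[gene]} if gene in pair_partners else set()))
        for organism in sorted({organism_of[s] for s in planted_membership[gene]}):
            if organism == "worm":
                continue
            src = _next_source(organism)
            planted_source[(organism, gene)] = src
            source_map[f"{organism}:{src}"] = targets

    # reserve enough worm genes for worm-study backgrounds before the rest of the
    # pool is spent on mapping targets for non-worm sources
    worm_needed = sum(
        sizes[sid] for sid in study_ids if organism_of[sid] == "worm"
    )
    worm_background = list(background_pool[:worm_needed])
    background_targets = list(background_pool[worm_needed:])
    target_cursor = 0
    for organism in ("yeast", "fly"):
        pool = universes[organism]
        for idx in range(used_sources[organism], len(pool)):
            if rng.random() >= config.orthology_coverage:
                continue
            fan_out = 2 if rng.random() < config.one_to_many_rate else 1
            if target_cursor + fan_out > len(background_targets):
                break  # worm universe exhausted; remaining sources stay unmapped
            targets = sorted(background_targets[target_cursor: target_cursor + fan_out])
            target_cursor += fan_out
            source_map[f"{organism}:{pool[idx]}"] = targets

    # --- hit lists ----------------------------------------------------------------
    worm_by_source: dict[str, dict[str, list[str]]] = {"yeast": {}, "fly": {}}
    for key, targets in source_map.items():
        organism, src = key.split(":", 1)
        worm_by_source[organism][src] = targets

    hits: dict[str, list[str]] = {sid: [] for sid in study_ids}
    for gene in planted:
        for sid in planted_membership[gene]:
            organism = organism_of[sid]
            if organism == "worm":
                hits[sid].append(gene)
            else:
                hits[sid].append(planted_source[(organism, gene)])

    used_worm: set[str] = set(planted) | set(pair_partners.values())
    mapped_background = {
        organism: sorted(worm_by_source[organism]) for organism in ("yeast", "fly")
    }
    unmapped_background = {
        organism: sorted(
            set(universes[organism]) - set(worm_by_source[organism])
            - {planted_source[k] for k in planted_source if k[0] == organism}
        )
        for organism in ("yeast", "fly")
    }
    # background source pools shared by the non-disjoint (independent uniform
    # draws per study) mode; planted genes and sources are already excluded
    free_worm = sorted(set(background_pool))
    free_sources = {
        organism: sorted(set(mapped_background[organism]) | set(unmapped_background[organism]))
        for organism in ("yeast", "fly")
    }

    for sid in study_ids:
        organism = organism_of[sid]
        need = sizes[sid] - len(hits[sid])
        if need < 0:
            raise ValidationError(f"study {sid}: planted hits exceed its size")
        if not config.disjoint_background:
            # each study draws its background uniformly without replacement from
            # the full shared pool, independently of every other study -- this is
            # exactly the sampling frame the overlap null model assumes
            pool = free_worm if organism == "worm" else free_sources[organism]
            if need > len(pool):
                raise ValidationError(f"{organism} universe too small for background draws")
            picked_idx = rng.choice(len(pool), size=need, replace=False)
            for i in picked_idx:
                hits[sid].append(pool[i])
        else:
            while need > 0:
                if organism == "worm":
                    if not worm_background:
                        raise ValidationError("worm universe too small for background draws")
                    gene = worm_background.pop(0)
                    if gene in used_worm:
                        continue
                    hits[sid].append(gene)
                    used_worm.add(gene)
                else:
                    candidates = mapped_background[organism]
                    picked = None
                    while candidates:
                        src = candidates.pop(0)
                        images = worm_by_source[organism][src]
                        if any(g in used_worm for g in images):
                            continue
                        picked = src
                        used_worm.update(images)
                        break
                    if picked is None:
                        pool = unmapped_background[organism]
                        if not pool:
                            raise ValidationError(
                                f"{organism} universe too small for background draws"
                            )
                        picked = pool.pop(0)
                    hits[sid].append(picked)
                need -= 1
        order = rng.permutation(len(hits[sid]))
        hits[sid] = [hits[sid][i] for i in order]

    # --- truth bookkeeping --------------------------------------------------------
    per_study_distinct: dict[str, int] = {}
    all_reference: set[str] = set()
    for sid in study_ids:
        organism = organism_of[sid]
        distinct: set[str] = set()
        for raw in hits[sid]:
            if organism == "worm":
                distinct.add(raw)
            else:
                distinct.update(worm_by_source[organism].get(raw, []))
        per_study_distinct[sid] = len(distinct)
        all_reference |= distinct

    classes = [f"Class {i + 1:02d}" for i in range(config.n_annotation_classes)]
    gene_class: dict[str, str] = {}
    for i, gene in enumerate(sorted(all_reference)):
        gene_class[gene] = classes[i % len(classes)] if classes else ""
    class_incidence: dict[str, list[str]] = {}
    for sid in study_ids:
        organism = organism_of[sid]
        seen: set[str] = set()
        for raw in hits[sid]:
            worms = [raw] if organism == "worm" else worm_by_source[organism].get(raw, [])
            seen.update(gene_class[g] for g in worms if gene_class.get(g))
        class_incidence[sid] = sorted(seen)

    run_id = f"synth-{config.seed}-{len(study_ids)}-{config.n_planted_shared}"
    truth = GroundTruth(
        run_id=run_id,
        planted_shared={g: planted_membership[g] for g in sorted(planted_membership)},
        paralogue_groups=sorted(paralogue_groups),
        source_map={k: source_map[k] for k in sorted(source_map)},
        study_sizes=dict(sorted(sizes.items())),
        per_study_distinct=dict(sorted(per_study_distinct.items())),
        distinct_reference_genes=len(all_reference),
        class_incidence=dict(sorted(class_incidence.items())),
        # JSON round-trip so tuples become lists: the in-memory truth then
        # compares equal to a manifest re-read from disk
        config=json.loads(json.dumps(asdict(config))),
    )

    _write_bundle(Path(out_dir), config, rng, study_ids, organism_of, sizes, hits,
                  source_map, gene_class, classes, truth)
    return truth


def _write_bundle(out, config, rng, study_ids, organism_of, sizes, hits,
                  source_map, gene_class, classes, truth) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "genes").mkdir(exist_ok=True)

    lines = ["study_id\torganism\tdisease_models\tconstruct\tscreen_type\t"
             "n_reported\tn_orthologues_expected\treference"]
    for sid in study_ids:
        models = sorted(
            DISEASE_CODES[i]
            for i in rng.choice(len(DISEASE_CODES), size=int(rng.integers(1, 3)), replace=False)
        )
        lines.append(
            f"{sid}\t{organism_of[sid]}\t{', '.join(models)}\tsynthetic construct\t"
            f"synthetic screen\t{sizes[sid]}\t{truth.per_study_distinct[sid]}\tsynthetic"
        )
    (out / "studies.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    for sid in study_ids:
        rows = ["raw_id\teffect\tnote"]
        for raw in hits[sid]:
            emitted = raw
            if (
                organism_of[sid] == "worm"
                and rng.random() < config.isoform_suffix_rate
            ):
                emitted = raw + "a"  # isoform-level spelling; normalization strips it
            effect = "suppressor" if rng.random() < 0.5 else "enhancer"
            rows.append(f"{emitted}\t{effect}\t")
        (out / "genes" / f"{sid}.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")

    prefix_of = {"worm": "cel", "yeast": "sce", "fly": "dme"}
    group_lines = []
    for i, key in enumerate(sorted(source_map), start=1):
        organism, src = key.split(":", 1)
        members = [f"{prefix_of[organism]}|{src}"] + [
            f"cel|{g}" for g in source_map[key]
        ]
        group_lines.append(f"G{i:04d}: " + " ".join(members))
    (out / "groups.txt").write_text("\n".join(group_lines) + "\n", encoding="utf-8")

    alias_lines = ["species\talias\tcanonical\tprovenance"]
    for i, gene in enumerate(sorted(truth.planted_shared)):
        alias_lines.append(f"worm\tsyn-{i + 1}\t{gene}\tsynthetic alias")
    (out / "aliases.tsv").write_text("\n".join(alias_lines) + "\n", encoding="utf-8")

    (out / "vocabulary.txt").write_text(
        "\n".join(classes) + ("\n" if classes else ""), encoding="utf-8"
    )
    ann_lines = ["gene\tfunctional_class\tsource"]
    for gene in sorted(gene_class):
        if gene_class[gene]:
            ann_lines.append(f"{gene}\t{gene_class[gene]}\tsynthetic")
    (out / "annotations.tsv").write_text("\n".join(ann_lines) + "\n", encoding="utf-8")

    ppi_lines = ["protein_a\tprotein_b\tprovenance"]
    labels = [f"PROT{i + 1}" for i in range(6)]
    for a, b in zip(labels, labels[1:]):
        ppi_lines.append(f"{a}\t{b}\tsynthetic")
    (out / "ppi_edges.tsv").write_text("\n".join(ppi_lines) + "\n", encoding="utf-8")

    (out / "truth.json").write_text(truth.to_json() + "\n", encoding="utf-8")


@dataclass
class RecoveryMetrics:
    precision: float
    recall: float
    n_planted: int
    n_found: int
    n_recovered: int
    vacuous: bool
    catalog_delta: int  # pipeline catalog size minus truth distinct count


def evaluate_recovery(
    truth: GroundTruth,
    overlaps,
    catalog=None,
    run_id: str | None = None,
) -> RecoveryMetrics:
    """Exact set comparison of recovered overlap genes against the planted set."""
    if run_id is not None and run_id != truth.run_id:
        raise ValidationError(
            f"run identifier mismatch: expected {truth.run_id!r}, got {run_id!r}"
        )
    planted = set(truth.planted_shared)
    for group in truth.paralogue_groups:
        planted.update(group)
    found = {g.value for entry in overlaps for g in entry.genes}
    recovered = found & planted
    vacuous = not planted
    recall = 1.0 if vacuous else len(recovered) / len(planted)
    precision = 1.0 if not found else len(recovered) / len(found)
    delta = 0
    if catalog is not None:
        delta = len(catalog) - truth.distinct_reference_genes
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        n_planted=len(planted),
        n_found=len(found),
        n_recovered=len(recovered),
        vacuous=vacuous,
        catalog_delta=delta,
    )
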