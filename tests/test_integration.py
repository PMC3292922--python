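import random

import pytest

from orthoverlap.errors import ValidationError
from orthoverlap.id_normalization import GeneId
from orthoverlap.integration import (
    find_overlaps,
    group_paralogue_entries,
    integrate_catalog,
    read_overlap_table,
    write_overlap_table,
)
from orthoverlap.orthology import OrthologyMap, map_study, read_pairwise_orthologs
from orthoverlap.study_catalog import RawGeneCall, Study


def build_worm_catalog(study_sets):
    """Assemble a catalog from plain per-study worm gene-name sets."""
    empty_map = OrthologyMap()
    studies, mapped = [], {}
    for sid, genes in study_sets.items():
        study = Study(
            study_id=sid,
            organism="worm",
            disease_models=frozenset({"P"}),
            n_reported=len(genes),
        )
        studies.append(study)
        calls = [RawGeneCall(study_id=sid, raw_id=g, species="worm") for g in sorted(genes)]
        mapped[sid], _ = map_study(study, calls, empty_map)
    return integrate_catalog(studies, mapped)


def brute_force_overlaps(study_sets, min_studies=2):
    """Independent oracle: direct enumeration over every gene."""
    membership = {}
    for sid, genes in study_sets.items():
        for g in genes:
            membership.setdefault(g, set()).add(sid)
    return {g: s for g, s in membership.items() if len(s) >= min_studies}


class TestIntegrateCatalog:
    def test_single_study_catalog_is_its_distinct_set(self):
        catalog = build_worm_catalog({"a": {"g1.1", "g2.1", "g1.1"}})
        assert len(catalog) == 2

    def test_evidence_conservation(self):
        study_sets = {"a": {"g1.1", "g2.1"}, "b": {"g2.1", "g3.1"}}
        catalog = build_worm_catalog(study_sets)
        assert catalog.n_evidence == 4

    def test_unknown_study_rejected(self):
        with pytest.raises(ValidationError, match="unknown studies"):
            integrate_catalog([], {"ghost": []})


class TestFindOverlaps:
    def test_three_study_worked_example(self):
        study_sets = {"A": {"g1.1", "g2.1"}, "B": {"g2.1", "g3.1"}, "C": {"g3.1"}}
        catalog = build_worm_catalog(study_sets)
        overlaps = find_overlaps(catalog)
        found = {e.sequence_names[0]: set(e.studies) for e in overlaps}
        assert found == {"g2.1": {"A", "B"}, "g3.1": {"B", "C"}}

    def test_single_study_yields_no_overlaps(self):
        catalog = build_worm_catalog({"a": {"g1.1", "g2.1"}})
        assert find_overlaps(catalog) == []

    def test_min_studies_below_two_rejected(self):
        catalog = build_worm_catalog({"a": {"g1.1"}})
        with pytest.raises(ValidationError):
            find_overlaps(catalog, min_studies=1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = random.Random(seed)
        n_studies = rng.randint(3, 6)
        universe = [f"w{i}.1" for i in range(30)]
        study_sets = {
            f"s{k}": set(rng.sample(universe, rng.randint(3, 12)))
            for k in range(n_studies)
        }
        min_studies = rng.choice([2, 2, 3])
        catalog = build_worm_catalog(study_sets)
        overlaps = find_overlaps(catalog, min_studies=min_studies)
        oracle = brute_force_overlaps(study_sets, min_studies)
        assert {e.sequence_names[0] for e in overlaps} == set(oracle)
        for entry in overlaps:
            assert set(entry.studies) == oracle[entry.sequence_names[0]]

    def test_monotone_in_min_studies(self):
        rng = random.Random(99)
        universe = [f"w{i}.1" for i in range(20)]
        study_sets = {f"s{k}": set(rng.sample(universe, 8)) for k in range(5)}
        catalog = build_worm_catalog(study_sets)
        sizes = [len(find_overlaps(catalog, min_studies=m)) for m in (2, 3, 4, 5)]
        assert sizes == sorted(sizes, reverse=True)

    def test_adding_a_study_never_removes_overlaps(self):
        base = {"a": {"g1.1", "g2.1"}, "b": {"g2.1", "g3.1"}}
        before = {
            e.sequence_names[0] for e in find_overlaps(build_worm_catalog(base))
        }
        base["c"] = {"g4.1", "g1.1"}
        after = {
            e.sequence_names[0] for e in find_overlaps(build_worm_catalog(base))
        }
        assert before <= after

    def test_sorted_by_study_count_then_name(self):
        study_sets = {
            "a": {"g1.1", "g2.1"},
            "b": {"g1.1", "g2.1"},
            "c": {"g1.1"},
        }
        overlaps = find_overlaps(build_worm_catalog(study_sets))
        assert [e.sequence_names[0] for e in overlaps] == ["g1.1", "g2.1"]


class TestGroupParalogues:
    def _fly_paralogue_catalog(self, tmp_path):
        pairs = tmp_path / "pairs.tsv"
        pairs.write_text(
            "source_species\tsource_id\ttarget_species\ttarget_id\tevidence\n"
            "fly\tCG31196\tworm\tF52D10.3\tppod\n"
            "fly\tCG31196\tworm\tM117.2\tppod\n"
        )
        omap = read_pairwise_orthologs(pairs)
        studies, mapped = [], {}
        for sid in ("f1", "f2"):
            study = Study(
                study_id=sid, organism="fly", disease_models=frozenset({"P"}), n_reported=1
            )
            studies.append(study)
            calls = [RawGeneCall(study_id=sid, raw_id="CG31196", species="fly")]
            mapped[sid], _ = map_study(study, calls, omap)
        return integrate_catalog(studies, mapped)

    def test_identical_fly_evidence_merges_worm_paralogues(self, tmp_path):
        catalog = self._fly_paralogue_catalog(tmp_path)
        overlaps = find_overlaps(catalog)
        assert len(overlaps) == 2
        grouped = group_paralogue_entries(overlaps, catalog)
        assert len(grouped) == 1
        (entry,) = grouped
        assert entry.sequence_names == ("F52D10.3", "M117.2")
        assert entry.studies == frozenset({"f1", "f2"})

    def test_different_evidence_does_not_merge(self):
        catalog = build_worm_catalog(
            {"a": {"g1.1", "g2.1"}, "b": {"g1.1", "g2.1"}}
        )
        overlaps = find_overlaps(catalog)
        grouped = group_paralogue_entries(overlaps, catalog)
        # worm-direct evidence: each gene is its own source, never merged
        assert len(grouped) == len(overlaps) == 2

    def test_curated_fixture_groups_to_34(self, table2_entries):
        assert len(table2_entries) == 35
        assert len(group_paralogue_entries(table2_entries)) == 34


class TestOverlapTableRoundTrip:
    def test_round_trip_preserves_entry_sets(self, tmp_path, table2_entries):
        grouped = group_paralogue_entries(table2_entries)
        out = tmp_path / "overlaps.tsv"
        write_overlap_table(grouped, out)
        back = read_overlap_table(out)
        assert len(back) == len(grouped)
        assert {e.genes for e in back} == {e.genes for e in grouped}
        assert {e.organisms for e in back} == {e.organisms for e in grouped}

    def test_empty_overlap_list_writes_header_only(self, tmp_path):
        out = tmp_path / "overlaps.tsv"
        write_overlap_table([], out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("sequence_names\t")

    def test_overlap_entries_subset_of_catalog(self):
        study_sets = {"a": {"g1.1", "g2.1"}, "b": {"g2.1"}}
        catalog = build_worm_catalog(study_sets)
        for entry in find_overlaps(catalog):
            for gene in entry.genes:
                assert gene in catalog.entries
                assert len(entry.studies) >= 2


def test_catalog_size_bounded_by_sum_of_per_study_distinct():
    study_sets = {"a": {"g1.1", "g2.1", "g3.1"}, "b": {"g2.1", "g4.1"}}
    catalog = build_worm_catalog(study_sets)
    assert len(catalog) <= sum(len(s) for s in study_sets.values())


def test_overlap_entry_requires_genes():
    from orthoverlap.integration import OverlapEntry

    with pytest.raises(ValidationError):
        OverlapEntry(
            genes=frozenset(),
            studies=frozenset({"a", "b"}),
            organisms=frozenset({"worm"}),
            disease_models=frozenset({"P"}),
        )


def test_paralogue_entry_shares_identical_evidence(table2_entries):
    grouped = group_paralogue_entries(table2_entries)
    multi = [e for e in grouped if len(e.genes) > 1]
    assert len(multi) == 1
    (entry,) = multi
    assert entry.sequence_names == ("F52D10.3", "M117.2")
    assert all(src.species != "worm" for _, src, _ in entry.evidence)


def _gene(value):
    return GeneId("worm", value)
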