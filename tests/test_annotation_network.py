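import random

import networkx as nx
import pytest

from orthoverlap.annotation_network import (
    attach_expression,
    attach_human_orthologues,
    build_functional_matrix,
    build_ppi_graph,
    connected_component,
    load_annotations,
    load_expression_table,
    load_vocabulary,
)
from orthoverlap.errors import ValidationError
from orthoverlap.fixtures import fixture_path, load_reference_expression
from orthoverlap.integration import find_overlaps, group_paralogue_entries
from tests.test_integration import build_worm_catalog


class TestLoadAnnotations:
    def test_packaged_vesicular_transport_class(self):
        annotations = load_annotations(
            fixture_path("table3_classes"), fixture_path("vocabulary")
        )
        vesicular = sorted(
            (a.gene.display_name or a.gene.value)
            for a in annotations
            if a.functional_class == "Vesicular transport"
        )
        assert vesicular == ["dhc-1", "rab-1", "sft-4", "tbc-20", "ykt-6"]

    def test_vocabulary_has_twelve_classes(self):
        assert len(load_vocabulary(fixture_path("vocabulary"))) == 12

    def test_empty_annotation_file(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("gene\tfunctional_class\tsource\n")
        assert load_annotations(path, fixture_path("vocabulary")) == []

    def test_class_outside_vocabulary_is_hard_error(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("gene\tfunctional_class\nrab-1\tTeleportation\n")
        with pytest.raises(ValidationError, match="Teleportation"):
            load_annotations(path, fixture_path("vocabulary"))


class TestFunctionalMatrix:
    def _annotated_catalog(self, tmp_path):
        catalog = build_worm_catalog(
            {"s1": {"g1.1", "g2.1"}, "s2": {"g3.1"}}
        )
        vocab = tmp_path / "vocab.txt"
        vocab.write_text("Molecular chaperones\nVesicular transport\n")
        ann = tmp_path / "ann.tsv"
        ann.write_text("gene\tfunctional_class\ng1.1\tMolecular chaperones\n")
        annotations = load_annotations(ann, vocab)
        return catalog, annotations, load_vocabulary(vocab)

    def test_cell_true_iff_witness_exists(self, tmp_path):
        catalog, annotations, vocab = self._annotated_catalog(tmp_path)
        matrix = build_functional_matrix(catalog, annotations, vocab)
        assert bool(matrix.loc["s1", "Molecular chaperones"]) is True
        assert bool(matrix.loc["s2", "Molecular chaperones"]) is False
        # reverse lookup: every true cell has an annotated witness gene
        class_genes = {a.functional_class: a.gene for a in annotations}
        for sid in matrix.index:
            for cls in matrix.columns:
                if matrix.loc[sid, cls]:
                    witness = class_genes[cls]
                    assert sid in catalog.entries[witness].studies

    def test_unused_vocabulary_class_kept_all_false(self, tmp_path):
        catalog, annotations, vocab = self._annotated_catalog(tmp_path)
        matrix = build_functional_matrix(catalog, annotations, vocab)
        assert "Vesicular transport" in matrix.columns
        assert not matrix["Vesicular transport"].any()

    def test_no_annotations_gives_all_false(self, tmp_path):
        catalog, _, vocab = self._annotated_catalog(tmp_path)
        matrix = build_functional_matrix(catalog, [], vocab)
        assert not matrix.to_numpy().any()


class TestHumanOrthologues:
    def test_chn_1_maps_to_chip_label(self, reference_orthology, table2_entries):
        chn = [e for e in table2_entries if e.sequence_names == ("T09B4.10",)]
        annotated, _ = attach_human_orthologues(chn, reference_orthology)
        assert annotated[0].human_orthologues == frozenset({"STUB1"})

    def test_every_curated_entry_has_a_human_orthologue(
        self, reference_orthology, table2_entries
    ):
        grouped = group_paralogue_entries(table2_entries)
        annotated, all_covered = attach_human_orthologues(grouped, reference_orthology)
        assert all_covered is True
        assert all(e.human_orthologues for e in annotated)

    def test_absent_entry_gets_empty_set_and_flag(self, reference_orthology):
        catalog = build_worm_catalog({"a": {"zz1.1"}, "b": {"zz1.1"}})
        overlaps = find_overlaps(catalog)
        annotated, all_covered = attach_human_orthologues(overlaps, reference_orthology)
        assert annotated[0].human_orthologues == frozenset()
        assert all_covered is False


class TestExpression:
    def test_bli_3_flagged_no(self, table2_entries):
        expression = load_reference_expression()
        bli3 = [e for e in table2_entries if e.sequence_names == ("F56C11.1",)]
        (annotated,) = attach_expression(bli3, expression)
        assert annotated.neuronal_expression == "no"

    def test_absent_gene_is_unknown(self, table2_entries):
        annotated = attach_expression(table2_entries[:1], {})
        assert annotated[0].neuronal_expression == "unknown"

    def test_curated_no_tally_is_three(self, table2_entries):
        # transcription tally: hda-1 "No?", bli-3 "No", phi-49 "No"
        expression = load_reference_expression()
        grouped = group_paralogue_entries(table2_entries)
        annotated = attach_expression(grouped, expression)
        assert sum(1 for e in annotated if e.neuronal_expression == "no") == 3

    def test_bad_value_is_hard_error(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("gene\tneuronal_expression\ng1.1\tmaybe\n")
        with pytest.raises(ValidationError, match="maybe"):
            load_expression_table(path)

    def test_spellings_normalized(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text(
            "gene\tneuronal_expression\na\tYes\nb\tNo?\nc\t?\nd\tno\n"
        )
        table = load_expression_table(path)
        assert table == {"a": "yes", "b": "no", "c": "unknown", "d": "no"}


class TestPPIGraph:
    def test_packaged_network_has_six_nodes(self):
        graph = build_ppi_graph(fixture_path("fig3_edges"))
        assert graph.number_of_nodes() == 6

    def test_duplicate_edges_collapse(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text(
            "protein_a\tprotein_b\tprovenance\nA\tB\tx\nA\tB\ty\nB\tA\tz\n"
        )
        graph = build_ppi_graph(path)
        assert graph.number_of_edges() == 1

    def test_self_loop_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "edges.tsv"
        path.write_text("protein_a\tprotein_b\tprovenance\nA\tA\tx\nA\tB\tx\n")
        graph = build_ppi_graph(path)
        assert graph.number_of_edges() == 1
        assert not any(graph.has_edge(n, n) for n in graph)

    def test_restriction_to_single_node(self):
        graph = build_ppi_graph(fixture_path("fig3_edges"), restrict_to={"CHIP"})
        assert graph.number_of_nodes() == 1
        assert graph.number_of_edges() == 0

    def test_restriction_never_grows_graph(self):
        full = build_ppi_graph(fixture_path("fig3_edges"))
        sub = build_ppi_graph(
            fixture_path("fig3_edges"), restrict_to={"CHIP", "Hsc70", "HSF1"}
        )
        assert sub.number_of_nodes() <= full.number_of_nodes()
        assert sub.number_of_edges() <= full.number_of_edges()

    def test_worm_cross_references_attached(self):
        graph = build_ppi_graph(
            fixture_path("fig3_edges"), nodes_path=fixture_path("fig3_nodes")
        )
        assert graph.nodes["CHIP"]["worm_gene"] == "T09B4.10"
        assert graph.nodes["Ube2D2"]["worm_name"] == "let-70"


class TestConnectedComponent:
    def test_chip_component_is_all_six_proteins(self):
        graph = build_ppi_graph(fixture_path("fig3_edges"))
        component = connected_component(graph, "CHIP")
        assert component == sorted(["CHIP", "DnaJB5", "HSF1", "Hsc70", "Ube2D2", "p97"])

    def test_isolated_node_is_its_own_component(self):
        graph = nx.Graph()
        graph.add_node("X")
        assert connected_component(graph, "X") == ["X"]

    def test_missing_seed_is_error(self):
        graph = build_ppi_graph(fixture_path("fig3_edges"))
        with pytest.raises(ValidationError, match="seed node"):
            connected_component(graph, "NOPE")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_reachability(self, seed):
        rng = random.Random(seed)
        graph = nx.gnp_random_graph(12, 0.2, seed=seed)
        graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
        node = f"N{rng.randrange(12)}"

        # oracle: exhaustive BFS by hand
        frontier, seen = [node], {node}
        while frontier:
            current = frontier.pop()
            for neighbor in graph.neighbors(current):
                if neighbor not in seen:
                    seen.add(neighbor)
                    frontier.append(neighbor)
        assert connected_component(graph, node) == sorted(seen)

    def test_components_partition_nodes(self):
        graph = build_ppi_graph(fixture_path("fig3_edges"))
        seen = []
        for node in graph.nodes:
            seen.extend(connected_component(graph, node))
        # every node counted exactly component-size times; union is the node set
        assert set(seen) == set(graph.nodes)
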