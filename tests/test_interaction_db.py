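"""Reading, validating, summarizing and exporting curated interaction tables."""

import textwrap

import pytest

from follinet.interaction_db import (
    build_network,
    db_from_network,
    db_from_records,
    export_network,
    load_network,
    read_interaction_table,
    species_incidence,
)


def write_table(tmp_path, body, name="table.tsv"):
    path = tmp_path / name
    path.write_text(textwrap.dedent(body))
    return path


HEADER = "source\tinteraction\ttarget\tspecies\tpmid\n"


class TestReadInteractionTable:
    def test_parses_distinct_rows(self, tmp_path):
        path = write_table(
            tmp_path,
            HEADER
            + "FSH\tactivates\tFSHR\tRodent\t11111111\n"
            + "KL\tinduces\tPI3K\tOvine\t22222222\n"
            + "cAMP\tbinds\tPKA\tBovine\t33333333\n",
        )
        db = read_interaction_table(path)
        assert len(db) == 3
        assert db.records[0].source == "FSH"
        assert db.records[1].species == "Ovine"
        assert db.n_duplicates_dropped == 0

    def test_exact_duplicates_collapse_with_count(self, tmp_path):
        row = "FSH\tactivates\tFSHR\tRodent\t11111111\n"
        db = read_interaction_table(write_table(tmp_path, HEADER + row + row))
        assert len(db) == 1
        assert db.n_duplicates_dropped == 1

    def test_empty_target_row_skipped_with_count(self, tmp_path):
        path = write_table(
            tmp_path, HEADER + "FSH\tactivates\t\tRodent\t1\n" + "KL\tbinds\tKIT\tOvine\t2\n"
        )
        db = read_interaction_table(path)
        assert len(db) == 1
        assert db.n_rows_skipped == 1

    def test_missing_target_column_is_hard_error(self, tmp_path):
        path = write_table(tmp_path, "source\tinteraction\nFSH\tactivates\n")
        with pytest.raises(ValueError, match="target"):
            read_interaction_table(path)

    def test_header_matching_is_case_insensitive_and_aliased(self, tmp_path):
        path = write_table(
            tmp_path,
            "Source Molecule\tInteraction\tTarget Molecule\tSpecies\tReference\n"
            "FSH\tactivates\tFSHR\tRodent\t11111111\n",
        )
        db = read_interaction_table(path)
        assert db.records[0].target == "FSHR"
        assert db.records[0].pmid == "11111111"

    def test_comma_delimiter_sniffed(self, tmp_path):
        path = write_table(
            tmp_path, "source,interaction,target,species,pmid\nA,binds,B,Rodent,1\n",
            name="table.csv",
        )
        assert len(read_interaction_table(path)) == 1

    def test_whitespace_canonicalized(self, tmp_path):
        path = write_table(tmp_path, HEADER + "  FSH  \tactivates\tFSH   R\tRodent\t1\n")
        rec = read_interaction_table(path).records[0]
        assert rec.source == "FSH"
        assert rec.target == "FSH R"

    def test_non_numeric_pmid_cleared(self, tmp_path):
        path = write_table(tmp_path, HEADER + "A\tbinds\tB\tRodent\tPMC123\n")
        assert read_interaction_table(path).records[0].pmid == ""


class TestSpeciesIncidence:
    def test_simple_proportion(self):
        rows = [("a", "i", "b", "Rodent", str(k)) for k in range(39)]
        rows += [("a", "i", "b", "Ovine", str(100 + k)) for k in range(61)]
        pct = species_incidence(db_from_records(rows))
        assert pct["Rodent"] == 39.00
        assert pct["Ovine"] == 61.00

    def test_single_record_is_100(self):
        pct = species_incidence(db_from_records([("a", "i", "b", "Ovine", "1")]))
        assert pct["Ovine"] == 100.00

    def test_percentages_sum_to_100(self):
        rows = [("a", "i", f"b{k}", ["Rodent", "Ovine", "Human"][k % 3], str(k)) for k in range(7)]
        assert abs(species_incidence(db_from_records(rows)).sum() - 100.0) <= 0.05

    def test_empty_db_errors(self):
        with pytest.raises(ValueError, match="no records"):
            species_incidence(db_from_records([]))


class TestBuildNetwork:
    def test_parallel_records_collapse_to_one_edge_merging_pmids(self):
        db = db_from_records(
            [("a", "activates", "b", "Rodent", "1"), ("a", "inhibits", "b", "Ovine", "2")]
        )
        net, counts = build_network(db)
        assert net.n_links == 1
        data = net.graph.edges["a", "b"]
        assert data["pmids"] == ["1", "2"]
        assert data["interactions"] == ["activates", "inhibits"]
        assert counts.n_records == 2

    def test_direction_preserved(self):
        net, _ = build_network(db_from_records([("a", "i", "b", "", "1"), ("b", "i", "a", "", "2")]))
        assert net.n_links == 2

    def test_self_loop_dropped_and_counted(self):
        net, counts = build_network(
            db_from_records([("a", "i", "a", "", "1"), ("a", "i", "b", "", "2")])
        )
        assert net.n_links == 1
        assert counts.n_self_loops_dropped == 1

    def test_empty_db_errors(self):
        with pytest.raises(ValueError):
            build_network(db_from_records([]))


class TestExportNetwork:
    @pytest.fixture
    def net(self):
        db = db_from_records(
            [("a", "activates", "b", "Rodent", "1"), ("b", "inhibits", "c", "Ovine", "2")]
        )
        return build_network(db)[0]

    def test_sif_line_format(self, net, tmp_path):
        path = export_network(net, tmp_path / "n.sif", "sif")
        assert path.read_text().splitlines()[0] == "a\tactivates\tb"

    @pytest.mark.parametrize("fmt", ["sif", "graphml", "edgelist"])
    def test_round_trip_preserves_node_and_edge_sets(self, net, tmp_path, fmt):
        path = export_network(net, tmp_path / f"n.{fmt}", fmt)
        back = load_network(path, fmt)
        assert back.nodes() == net.nodes()
        assert back.edges() == net.edges()

    def test_graphml_round_trip_preserves_annotations(self, net, tmp_path):
        path = export_network(net, tmp_path / "n.graphml", "graphml")
        back = load_network(path, "graphml")
        assert back.graph.edges["a", "b"]["pmids"] == ["1"]
        assert back.graph.edges["b", "c"]["interactions"] == ["inhibits"]

    def test_unknown_format_lists_supported(self, net, tmp_path):
        with pytest.raises(ValueError, match="sif.*graphml.*edgelist"):
            export_network(net, tmp_path / "x", "gexf")

    def test_empty_network_errors(self, tmp_path):
        import networkx as nx

        from follinet.interaction_db import SignalingNetwork

        with pytest.raises(ValueError):
            export_network(SignalingNetwork(nx.DiGraph()), tmp_path / "x.sif", "sif")


def test_build_is_idempotent_through_export(tmp_path):
    """Rebuilding from an exported edge list reproduces node/edge sets."""
    db = db_from_records(
        [("a", "i", "b", "Rodent", "1"), ("b", "i", "c", "Ovine", "2"), ("c", "i", "a", "", "3")]
    )
    net, _ = build_network(db)
    net2, _ = build_network(db_from_network(net))
    assert net2.nodes() == net.nodes()
    assert net2.edges() == net.edges()


def test_edge_and_node_count_bounds():
    rows = [("a", "i", "b", "", "1"), ("a", "j", "b", "", "2"), ("b", "i", "c", "", "3")]
    db = db_from_records(rows)
    net, _ = build_network(db)
    assert net.n_links <= len(db)
    assert net.n_nodes <= 2 * len(db)
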