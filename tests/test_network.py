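import numpy as np
import pytest

from anatonet import (GeneNetwork, degree_table, filter_network, read_network,
                      read_string_links, score_histogram, select_cutoff,
                      write_network)
from anatonet.network import read_id_mapping

from oracles import count_above


def _net(edges, **kw):
    return GeneNetwork.from_edges(edges, **kw)


def _edge_set(net):
    return {(min(u, v), max(u, v), s) for u, v, s in net.edges()}


class TestStringLinks:
    def test_score_scale_and_mapping(self, tmp_path):
        links = tmp_path / "links.txt"
        links.write_text("protein1 protein2 combined_score\np1 p2 700\n")
        net = read_string_links(links, {"p1": "g1", "p2": "g2"})
        assert net.score("g1", "g2") == pytest.approx(0.700)

    def test_reverse_duplicates_collapse(self, tmp_path):
        links = tmp_path / "links.txt"
        links.write_text("a b 700\nb a 700\n")
        net = read_string_links(links)
        assert net.n_edges == 1

    def test_conflicting_duplicates_keep_max_with_warning(self, tmp_path):
        links = tmp_path / "links.txt"
        links.write_text("a b 700\nb a 900\n")
        with pytest.warns(UserWarning, match="conflicting"):
            net = read_string_links(links)
        assert net.score("a", "b") == pytest.approx(0.9)

    def test_unmapped_ids_kept_raw_and_counted(self, tmp_path):
        links = tmp_path / "links.txt"
        rows = [("p1", "p2", 700), ("p1", "p3", 650), ("p2", "p3", 400),
                ("p1", "p4", 800), ("p2", "p4", 500)]
        links.write_text("protein1 protein2 combined_score\n" +
                         "".join(f"{a} {b} {s}\n" for a, b, s in rows))
        id_map = {"p1": "g1", "p2": "g2", "p3": "g3"}  # p4 unmapped
        net = read_string_links(links, id_map)
        assert net.n_edges == 5
        assert "p4" in net.nodes()
        assert net.unmapped_ids == {"p4"}

    def test_malformed_rows_skipped(self, tmp_path):
        links = tmp_path / "links.txt"
        links.write_text("a b 700\nbroken\na c xyz\na d 500\n")
        net = read_string_links(links)
        assert net.n_edges == 2

    def test_id_mapping_reader(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("#header\np1\tg1\np2\tg2\n")
        assert read_id_mapping(path) == {"p1": "g1", "p2": "g2"}


class TestFilterNetwork:
    def test_strict_inequality_at_cutoff(self):
        net = _net([("a", "b", 0.69), ("a", "c", 0.70), ("a", "d", 0.71)])
        filtered = filter_network(net, 0.7)
        assert filtered.n_edges == 1
        assert filtered.score("a", "d") == pytest.approx(0.71)
        assert filtered.cutoff == 0.7

    def test_zero_cutoff_keeps_positive_scores(self):
        net = _net([("a", "b", 0.1), ("b", "c", 0.9)])
        assert filter_network(net, 0.0).n_edges == 2

    def test_isolated_nodes_dropped(self):
        net = _net([("a", "b", 0.9), ("c", "d", 0.1)])
        filtered = filter_network(net, 0.5)
        assert filtered.nodes() == {"a", "b"}

    def test_idempotent_at_same_cutoff(self):
        rng = np.random.default_rng(0)
        net = _net([(f"a{i}", f"b{i}", s) for i, s in enumerate(rng.random(100))])
        once = filter_network(net, 0.4)
        twice = filter_network(once, 0.4)
        assert _edge_set(once) == _edge_set(twice)

    def test_counting_matches_oracle(self):
        rng = np.random.default_rng(1)
        scores = rng.random(100)
        net = _net([(f"a{i}", f"b{i}", s) for i, s in enumerate(scores)])
        for cutoff in (0.1, 0.5, 0.9):
            assert filter_network(net, cutoff).n_edges == count_above(scores, cutoff)

    def test_cutoff_out_of_range(self):
        net = _net([("a", "b", 0.5)])
        with pytest.raises(ValueError):
            filter_network(net, 1.5)


class TestHistogram:
    def test_hand_binning(self):
        net = _net([("a", "b", 0.1), ("c", "d", 0.1), ("e", "f", 0.5), ("g", "h", 0.9)])
        hist = score_histogram(net, bins=10)
        assert hist["count"].tolist() == [0, 2, 0, 0, 0, 1, 0, 0, 0, 1]

    def test_empty_network(self):
        hist = score_histogram(GeneNetwork(), bins=10)
        assert hist["count"].sum() == 0

    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        net = _net([(f"a{i}", f"b{i}", s) for i, s in enumerate(rng.random(250))])
        assert score_histogram(net, bins=17)["count"].sum() == net.n_edges


class TestSelectCutoff:
    def test_continuum_lands_in_band(self):
        net = _net([(f"a{i}", f"b{i}", (i + 1) / 1000) for i in range(1000)])
        cutoff = select_cutoff(net, (100, 200))
        kept = filter_network(net, cutoff).n_edges
        assert 100 <= kept <= 200

    def test_tie_degenerate_warns(self):
        net = _net([(f"a{i}", f"b{i}", 0.5) for i in range(20)])
        with pytest.warns(UserWarning, match="no cutoff"):
            cutoff = select_cutoff(net, (5, 15))
        assert filter_network(net, cutoff).n_edges in (0, 20)

    def test_matches_exhaustive_scan_with_duplicated_scores(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(1, 20, size=200) / 20.0  # heavy ties
        net = _net([(f"a{i}", f"b{i}", s) for i, s in enumerate(scores)])
        band = (40, 80)
        cutoff = select_cutoff(net, band)
        kept = count_above(scores, cutoff)
        achievable = {count_above(scores, c) for c in np.concatenate(([0.0], np.unique(scores)))}
        in_band = {c for c in achievable if band[0] <= c <= band[1]}
        if in_band:
            assert band[0] <= kept <= band[1]

    def test_invalid_band_rejected(self):
        net = _net([("a", "b", 0.5), ("c", "d", 0.7)])
        with pytest.raises(ValueError):
            select_cutoff(net, (5, 2))


class TestDegreesAndIO:
    def test_triangle_and_star(self):
        tri = _net([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        assert degree_table(tri)["degree"].tolist() == [2, 2, 2]
        star = _net([("hub", f"s{i}", 1) for i in range(4)])
        degrees = dict(degree_table(star).itertuples(index=False))
        assert degrees["hub"] == 4
        assert all(degrees[f"s{i}"] == 1 for i in range(4))

    def test_degree_sum_is_twice_edges(self):
        rng = np.random.default_rng(4)
        pairs = {(f"n{i}", f"n{j}") for i, j in rng.integers(0, 40, size=(120, 2)) if i != j}
        net = _net([(u, v, 0.5) for u, v in pairs])
        assert degree_table(net)["degree"].sum() == 2 * net.n_edges

    def test_degree_matches_adjacency_oracle(self):
        rng = np.random.default_rng(5)
        pairs = {(f"n{i}", f"n{j}") for i, j in rng.integers(0, 30, size=(80, 2)) if i != j}
        net = _net([(u, v, 0.5) for u, v in pairs])
        for gene, degree in degree_table(net).itertuples(index=False):
            assert degree == len(net.graph[gene])

    def test_read_write_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(6)
        net = _net([(f"a{i}", f"b{i}", float(s)) for i, s in enumerate(rng.random(50))])
        path = tmp_path / "net.tsv"
        write_network(net, path)
        again = read_network(path)
        assert _edge_set(again) == _edge_set(net)
        write_network(again, tmp_path / "net2.tsv")
        assert (tmp_path / "net2.tsv").read_text() == path.read_text()

    def test_gzip_round_trip(self, tmp_path):
        net = _net([("a", "b", 0.123456789)])
        path = tmp_path / "net.tsv.gz"
        write_network(net, path)
        assert read_network(path).score("a", "b") == 0.123456789

    def test_no_self_loops(self):
        net = _net([("a", "a", 0.9), ("a", "b", 0.5)])
        assert net.n_edges == 1
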