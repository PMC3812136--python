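import networkx as nx
import numpy as np
import pytest

from ffloops.coreg_network import (
    build_network,
    degree_and_hub,
    ego_subnetwork,
    export_graphml,
    export_sif,
    occurrence_ranking,
    powerlaw_exponent,
)
from ffloops.ffl_builder import FFL, COMPOSITE_FFL, MIRNA_FFL, TF_FFL


def tf_ffl(t, m, g):
    return FFL(TF_FFL, t, m, g)


class TestBuildNetwork:
    def test_single_tf_ffl(self):
        net = build_network([tf_ffl("t", "m", "g")])
        assert len(net.nodes) == 3
        assert net.n_edges == 3
        assert net.node_type("t") == "TF"
        assert net.node_type("m") == "miRNA"
        assert net.node_type("g") == "gene"

    def test_shared_mirna_counted_once(self):
        net = build_network([tf_ffl("t1", "m", "g1"), tf_ffl("t2", "m", "g2")])
        assert net.nodes.count("m") == 1
        assert len(net.nodes) == 5

    def test_empty_list(self):
        assert build_network([]).n_edges == 0

    def test_composite_contributes_four_edges(self):
        net = build_network([FFL(COMPOSITE_FFL, "t", "m", "g")])
        assert net.n_edges == 4

    def test_edge_count_bound(self):
        ffls = [tf_ffl("t", "m", f"g{i}") for i in range(4)]
        ffls.append(FFL(COMPOSITE_FFL, "t2", "m2", "g0"))
        net = build_network(ffls)
        assert net.n_edges <= 3 * 4 + 4

    def test_mirna_regulation_edges_originate_from_mirnas(self):
        net = build_network(
            [FFL(MIRNA_FFL, "t", "m", "g"), FFL(COMPOSITE_FFL, "t2", "m2", "g")]
        )
        for src, _, data in net.graph.edges(data=True):
            if data["regulation_type"] == "miRNA_regulation":
                assert net.node_type(src) == "miRNA"


class TestDegreeAndHub:
    def test_star(self):
        ffls = [tf_ffl("t", "c", f"g{i}") for i in range(5)]
        net = build_network(ffls)
        degrees, hub = degree_and_hub(net)
        # tf and mirna both touch every gene plus each other; tie -> "c" wins
        assert degrees["c"] == degrees["t"] == 6
        assert hub == "c"

    def test_tie_breaks_lexicographically(self):
        net = build_network([tf_ffl("a", "b", "g")])
        degrees, hub = degree_and_hub(net)
        assert degrees == {"a": 2, "b": 2, "g": 2}
        assert hub == "a"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            degree_and_hub(build_network([]))

    def test_planted_hub_simulation(self):
        rng = np.random.default_rng(0)
        ffls = [tf_ffl(f"t{rng.integers(20)}", "hub-mir", f"g{i}") for i in range(40)]
        ffls += [
            tf_ffl(f"t{rng.integers(20)}", f"m{rng.integers(10)}", f"h{i}")
            for i in range(60)
        ]
        degrees, hub = degree_and_hub(build_network(ffls))
        assert hub == "hub-mir"

    def test_ego_of_hub_has_degree_plus_one_nodes(self):
        ffls = [tf_ffl(f"t{i % 3}", "m", f"g{i}") for i in range(6)]
        net = build_network(ffls)
        degrees, hub = degree_and_hub(net)
        ego = ego_subnetwork(net, hub)
        assert len(ego.nodes) == degrees[hub] + 1


class TestOccurrenceRanking:
    def test_simple_count(self):
        ffls = [tf_ffl("t", "m", f"g{i}") for i in range(3)]
        ffls += [tf_ffl("t2", "m2", "g9")] * 1
        df = occurrence_ranking({"d": ffls})
        assert df.at["t", "d_ffls"] == 3
        assert df.at["m", "d_ffls"] == 3

    def test_absent_regulator_unranked(self):
        df = occurrence_ranking(
            {"a": [tf_ffl("t", "m", "g")], "b": [tf_ffl("t2", "m2", "g")]}
        )
        import pandas as pd

        assert df.at["t", "b_ffls"] == 0
        assert pd.isna(df.at["t", "b_rank"])

    def test_tied_counts_rank_lexicographically_within_kind(self):
        # miRNA occurrence profile shaped like a top-regulator table:
        # 41, 19, 16, 16 (tie), 13; miRNAs are ranked among miRNAs only
        counts = {"mA": 41, "mB": 19, "mD": 16, "mC": 16, "mE": 13}
        ffls = []
        for i, (mid, c) in enumerate(counts.items()):
            ffls += [tf_ffl(f"t{i}", mid, f"g{i}_{j}") for j in range(c)]
        df = occurrence_ranking({"d": ffls})
        ranks = {rid: int(df.at[rid, "d_rank"]) for rid in counts}
        assert ranks == {"mA": 1, "mB": 2, "mC": 3, "mD": 4, "mE": 5}
        assert int(df.at["t0", "d_rank"]) == 1  # TFs ranked separately


class TestEgoSubnetwork:
    def test_star_center_returns_whole_star(self):
        ffls = [tf_ffl("t", "m", f"g{i}") for i in range(4)]
        net = build_network(ffls)
        ego = ego_subnetwork(net, "m")
        assert set(ego.nodes) == set(net.nodes)

    def test_leaf_keeps_only_incident_edge(self):
        net = build_network([tf_ffl("t", "m", "g1"), tf_ffl("t", "m", "g2")])
        ego = ego_subnetwork(net, "g1")
        assert set(ego.nodes) == {"g1", "t", "m"}
        assert ego.n_edges == 2  # t->g1 and m->g1 only

    def test_triangle_excludes_neighbor_neighbor_edges(self):
        net = build_network([tf_ffl("t", "m", "g")])
        ego = ego_subnetwork(net, "g")
        # t->m exists in the parent network but is not center-incident
        assert ego.n_edges == 2

    def test_unknown_node_raises(self):
        with pytest.raises(KeyError):
            ego_subnetwork(build_network([tf_ffl("t", "m", "g")]), "zzz")


class TestPowerlawExponent:
    def test_exact_inverse_square_distribution(self):
        # count(k) = 256 / k^2 exactly, over k in {1, 2, 4, 8, 16}
        degrees = {}
        node = 0
        for k in (1, 2, 4, 8, 16):
            for _ in range(256 // k ** 2):
                degrees[f"n{node}"] = k
                node += 1
        assert powerlaw_exponent(degrees) == pytest.approx(2.0, abs=1e-6)

    def test_uniform_distribution_near_zero(self):
        degrees = {f"n{i}": 1 + i % 5 for i in range(500)}
        assert abs(powerlaw_exponent(degrees)) < 1e-9

    def test_preferential_attachment_range(self):
        g = nx.barabasi_albert_graph(1000, 2, seed=1)
        degrees = {str(n): d for n, d in g.degree()}
        assert 1.5 <= powerlaw_exponent(degrees) <= 3.5

    def test_too_few_degree_values_raise(self):
        with pytest.raises(ValueError):
            powerlaw_exponent({"a": 1, "b": 1, "c": 2})


class TestExports:
    def test_sif_lines(self, tmp_path):
        net = build_network([tf_ffl("t", "m", "g")])
        path = tmp_path / "net.sif"
        export_sif(net, path)
        lines = set(path.read_text().strip().splitlines())
        assert lines == {
            "t\tTF_regulation\tg",
            "t\tTF_regulation\tm",
            "m\tmiRNA_regulation\tg",
        }

    def test_graphml_round_trip_attributes(self, tmp_path):
        net = build_network([FFL(COMPOSITE_FFL, "t", "m", "g")])
        path = tmp_path / "net.graphml"
        export_graphml(net, path)
        g = nx.read_graphml(path)
        assert g.nodes["m"]["node_type"] == "miRNA"
        assert g.number_of_edges() == 4
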