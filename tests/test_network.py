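import networkx as nx
import numpy as np
import pytest

from drugrep import (
    GeneNetwork,
    GeneSet,
    SignatureLibrary,
    degree_matched_null,
    first_neighbor_subnetwork,
    load_network,
    mean_min_distance,
    proximity_z,
    rank_drugs_by_proximity,
)


class TestLoadNetwork:
    def test_path_graph_degrees(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("a\tb\nb\tc\nc\td\n")
        net = load_network(f)
        assert sorted(net.degree_index.values()) == [1, 1, 2, 2]
        assert len(set(net.components.values())) == 1

    def test_duplicates_collapse_and_self_loops_drop(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("a\tb\na\tb\na\ta\n")
        net = load_network(f)
        assert net.graph.number_of_edges() == 1
        assert net.n_self_loops_removed == 1
        assert net.n_duplicates_collapsed == 1

    def test_malformed_row_names_line(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("a\tb\nonlyone\n")
        with pytest.raises(ValueError, match=":2"):
            load_network(f)

    def test_empty_edge_list_errors(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("\n")
        with pytest.raises(ValueError, match="empty"):
            load_network(f)


class TestMeanMinDistance:
    def test_path_graph_worked_example(self, path_network):
        res = mean_min_distance(["a", "d"], ["b"], path_network, min_drug_size=0)
        assert res.d_obs == pytest.approx(1.5)

    def test_drug_subset_of_query_gives_zero(self, path_network):
        res = mean_min_distance(["a", "b"], ["a", "b", "c"], path_network,
                                min_drug_size=0)
        assert res.d_obs == 0.0

    def test_isolated_component_gene_dropped(self):
        net = GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("x", "y")])
        res = mean_min_distance(["a", "x"], ["b"], net, min_drug_size=0)
        assert res.n_drug_dropped == 1
        assert res.d_obs == pytest.approx(1.0)

    def test_size_filter_enforced_but_overridable(self, path_network):
        with pytest.raises(ValueError, match="more than"):
            mean_min_distance(["a", "d"], ["b"], path_network)

    def test_missing_drug_or_disconnected_query_errors(self, path_network):
        with pytest.raises(ValueError, match="drug gene"):
            mean_min_distance(["zz"], ["b"], path_network, min_drug_size=0)
        net = GeneNetwork.from_edges([("a", "b"), ("x", "y")])
        with pytest.raises(ValueError, match="connected"):
            mean_min_distance(["a"], ["x"], net, min_drug_size=0)

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        # brute-force all-pairs oracle on 60 random graphs up to 50 nodes
        for _ in range(60):
            n = int(rng.integers(5, 51))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
            if g.number_of_edges() == 0:
                continue
            net = GeneNetwork(graph=g)
            nodes = sorted(g.nodes)
            drug = list(rng.choice(nodes, size=min(5, n), replace=False))
            query = list(rng.choice(nodes, size=min(4, n), replace=False))
            lengths = dict(nx.all_pairs_shortest_path_length(g))
            expected = []
            for a in {d.upper() for d in drug}:
                ds = [lengths[a][b] for b in {q.upper() for q in query}
                      if b in lengths.get(a, {})]
                if ds:
                    expected.append(min(ds))
            if not expected:
                continue
            res = mean_min_distance(drug, query, net, min_drug_size=0)
            assert res.d_obs == pytest.approx(np.mean(expected))

    def test_enlarging_query_never_increases_distance(self, benchmark_fixture):
        net = benchmark_fixture.network
        nodes = sorted(net.graph.nodes)
        drug = nodes[:15]
        small = nodes[50:60]
        large = small + nodes[60:80]
        d_small = mean_min_distance(drug, small, net, min_drug_size=0).d_obs
        d_large = mean_min_distance(drug, large, net, min_drug_size=0).d_obs
        assert d_large <= d_small


class TestDegreeMatchedNull:
    def test_fixed_seed_is_bit_identical(self, benchmark_fixture):
        net = benchmark_fixture.network
        drug = sorted(net.graph.nodes)[:12]
        query = benchmark_fixture.disease.genes
        a = degree_matched_null(drug, query, net, n_perm=50, seed=3)
        b = degree_matched_null(drug, query, net, n_perm=50, seed=3)
        assert np.array_equal(a, b)

    def test_zero_permutations_error(self, benchmark_fixture):
        net = benchmark_fixture.network
        with pytest.raises(ValueError, match="positive"):
            degree_matched_null(sorted(net.graph.nodes)[:12],
                                benchmark_fixture.disease.genes, net, n_perm=0)


class TestProximityZ:
    def test_planted_drug_is_significant(self, benchmark_fixture):
        fx = benchmark_fixture
        sig = fx.library.filter(id="drugpos01")[0]
        res = proximity_z(sig, fx.disease, fx.network, n_perm=200, seed=11)
        assert res.z < -2.33 and res.significant
        assert res.p_empirical <= 1.0
        assert res.z == pytest.approx((res.d_obs - res.null_mean) / res.null_sd)

    def test_deterministic_under_fixed_seed(self, benchmark_fixture):
        fx = benchmark_fixture
        sig = fx.library.filter(id="drugneg01")[0]
        a = proximity_z(sig, fx.disease, fx.network, n_perm=100, seed=5)
        b = proximity_z(sig, fx.disease, fx.network, n_perm=100, seed=5)
        assert a == b


class TestRankDrugsByProximity:
    def test_planted_positives_rank_top_quartile(self, benchmark_fixture):
        fx = benchmark_fixture
        results = rank_drugs_by_proximity(fx.library, fx.disease, fx.network,
                                          n_perm=200, seed=2)
        quartile = max(1, len(results) // 4)
        top_ids = {r.drug_id for r in results[: quartile + 1]}
        positives = {d for d, lab in fx.labels.items() if lab}
        assert positives <= top_ids

    def test_single_drug_percentile_convention(self, benchmark_fixture):
        fx = benchmark_fixture
        lib = SignatureLibrary([fx.library.sorted()[0]])
        (res,) = rank_drugs_by_proximity(lib, fx.disease, fx.network,
                                         n_perm=100, seed=1)
        assert res.percentile == 1.0 and res.rank == 1

    def test_all_drugs_filtered_errors(self, benchmark_fixture, toy_library):
        with pytest.raises(ValueError, match="filtered"):
            rank_drugs_by_proximity(toy_library, benchmark_fixture.disease,
                                    benchmark_fixture.network, n_perm=100, seed=1)


class TestFirstNeighborSubnetwork:
    def test_shared_gene_is_overlap(self, path_network):
        nodes, edges = first_neighbor_subnetwork(["a"], ["a"], path_network)
        assert nodes.values.tolist() == [["A", "overlap"]]
        assert edges.empty

    def test_adjacent_roles_on_edge(self):
        net = GeneNetwork.from_edges([("a", "b")])
        nodes, edges = first_neighbor_subnetwork(["a"], ["b"], net)
        roles = dict(nodes.values.tolist())
        assert roles == {"A": "drug_adjacent_to_query", "B": "query_adjacent_to_drug"}
        assert edges.values.tolist() == [["A", "B"]]

    def test_empty_result_is_empty_tables(self, path_network):
        nodes, edges = first_neighbor_subnetwork(["a"], ["d"], path_network)
        assert nodes.empty and edges.empty

    def test_matches_adjacency_oracle_on_random_fixture(self, benchmark_fixture, rng):
        net = benchmark_fixture.network
        all_nodes = sorted(net.graph.nodes)
        drug = set(rng.choice(all_nodes, size=25, replace=False))
        query = set(rng.choice(all_nodes, size=25, replace=False))
        nodes, _ = first_neighbor_subnetwork(drug, query, net)
        expected = set()
        for d in drug:
            if d in query or any(n in query for n in net.graph.adj[d]):
                expected.add(d)
        for q in query:
            if q in drug or any(n in drug for n in net.graph.adj[q]):
                expected.add(q)
        assert set(nodes["name"]) == expected
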