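"""Centrality algorithms against hand evaluations and brute-force oracles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

import _oracles as orc
from keygenet import InputError
from keygenet.centrality import (
    COMPARISON_ALGORITHMS,
    INTEGRATION_ALGORITHMS,
    betweenness,
    closeness,
    degree,
    ec_centricity,
    epc,
    katz,
    laplacian_centrality,
    mnc,
    radiality,
    slc,
    stress,
)
from conftest import random_connected_graph, random_graph


def as_dict(table):
    return table.scores.to_dict()


class TestHandExamples:
    def test_degree_triangle_and_star(self, triangle, star4):
        assert as_dict(degree(triangle)) == {0: 2, 1: 2, 2: 2}
        d = as_dict(degree(star4))
        assert d[0] == 4 and all(d[i] == 1 for i in range(1, 5))

    def test_degree_handshake(self):
        G = random_graph(30, 0.2, seed=4)
        assert sum(as_dict(degree(G)).values()) == 2 * G.number_of_edges()

    def test_laplacian_triangle(self, triangle):
        # 2^2 + 2 + 2*(2+2) = 14 at every node
        assert as_dict(laplacian_centrality(triangle)) == {0: 14, 1: 14, 2: 14}

    def test_laplacian_isolated_node_zero(self):
        G = nx.Graph()
        G.add_node("a")
        G.add_edge("b", "c")
        assert as_dict(laplacian_centrality(G))["a"] == 0

    def test_mnc_star_center_one(self, star4):
        assert as_dict(mnc(star4))[0] == 1

    def test_mnc_triangle_two(self, triangle):
        assert as_dict(mnc(triangle)) == {0: 2, 1: 2, 2: 2}

    def test_katz_edgeless_all_one(self):
        G = nx.empty_graph(4)
        assert as_dict(katz(G, 0.3)) == {i: pytest.approx(1.0) for i in range(4)}

    def test_katz_two_nodes_closed_form(self, two_nodes_one_edge):
        # (I - 0.1 A)^{-1} row sum = (1 + 0.1) / (1 - 0.01) = 10/9
        d = as_dict(katz(two_nodes_one_edge, 0.1))
        assert d[0] == pytest.approx(10 / 9, abs=1e-12)
        assert d[1] == pytest.approx(10 / 9, abs=1e-12)

    def test_katz_divergence_error_names_bound(self, triangle):
        with pytest.raises(ValueError, match="lambda_max"):
            katz(triangle, alpha=0.6)  # spectral radius 2 -> bound 0.5

    def test_radiality_complete_graph_ones(self):
        d = as_dict(radiality(nx.complete_graph(5)))
        assert all(v == pytest.approx(1.0) for v in d.values())

    def test_radiality_path3(self, path3):
        d = as_dict(radiality(path3))
        assert d[1] == pytest.approx(2.0)
        assert d[0] == d[2] == pytest.approx(1.5)

    def test_radiality_requires_connected(self):
        G = nx.Graph()
        G.add_edge(1, 2)
        G.add_node(3)
        with pytest.raises(InputError, match="extract_core"):
            radiality(G)
        with pytest.raises(InputError):
            radiality(nx.empty_graph(1))

    def test_slc_isolated_zero_triangle_eight(self, triangle):
        assert as_dict(slc(triangle)) == {0: 8, 1: 8, 2: 8}
        G = nx.Graph()
        G.add_node("a")
        assert as_dict(slc(G))["a"] == 0

    def test_shortest_path_family_on_k5(self):
        K5 = nx.complete_graph(5)
        assert all(v == 1.0 for v in as_dict(ec_centricity(K5)).values())
        assert all(v == 0.0 for v in as_dict(betweenness(K5)).values())

    def test_path3_middle_betweenness_and_stress(self, path3):
        assert as_dict(betweenness(path3))[1] == pytest.approx(1.0)
        assert as_dict(stress(path3))[1] == pytest.approx(1.0)

    def test_ec_centricity_reciprocal_eccentricity_on_paths(self):
        # node at the end of a 9-node path has eccentricity 8 -> 0.125
        P9 = nx.path_graph(9)
        assert as_dict(ec_centricity(P9))[0] == pytest.approx(1 / 8)
        P10 = nx.path_graph(10)
        assert as_dict(ec_centricity(P10))[0] == pytest.approx(1 / 9, abs=5e-4)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_laplacian_equals_energy_drop_exactly(self, seed):
        G = random_graph(8, 0.35, seed)
        assert as_dict(laplacian_centrality(G)) == orc.laplacian_energy_drop(G)

    @pytest.mark.parametrize("seed", range(25))
    def test_mnc_and_slc_match_bfs_oracles(self, seed):
        G = random_graph(8, 0.3, seed)
        assert as_dict(mnc(G)) == orc.mnc_brute(G)
        assert as_dict(slc(G)) == orc.slc_brute(G)

    @pytest.mark.parametrize("seed", range(25))
    def test_distance_family_matches_bfs_oracles(self, seed):
        G = random_connected_graph(8, 0.3, seed)
        for impl, oracle in [
            (radiality, orc.radiality_brute),
            (closeness, orc.closeness_brute),
            (betweenness, orc.betweenness_brute),
            (stress, orc.stress_brute),
            (ec_centricity, orc.ec_centricity_brute),
        ]:
            got = as_dict(impl(G))
            want = oracle(G)
            assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_katz_closed_form_matches_series(self, seed):
        G = random_graph(8, 0.3, seed)
        got = as_dict(katz(G, alpha=0.1))
        want = orc.katz_series(G, alpha=0.1, n_terms=200)
        assert got == pytest.approx(want, abs=1e-10)


class TestEPC:
    def test_edgeless_scores_one_over_v(self):
        G = nx.empty_graph(5)
        d = as_dict(epc(G, seed=0))
        assert all(v == pytest.approx(0.2) for v in d.values())

    def test_two_node_analytic_expectation(self, two_nodes_one_edge):
        # keep probability 0.5: E[score] = (1 + 0.5)/2 = 0.75
        d = as_dict(epc(two_nodes_one_edge, n_reduced=1000, seed=1))
        se = 0.25 / np.sqrt(1000)  # per-replicate sd is 1/4
        for v in d.values():
            assert abs(v - 0.75) <= 3 * se

    def test_matches_exhaustive_enumeration(self):
        for seed in range(5):
            G = random_graph(5, 0.5, seed)
            if G.number_of_edges() > 6:
                continue
            mean, sd = orc.epc_exhaustive(G)
            d = as_dict(epc(G, n_reduced=1000, seed=seed))
            for x in G.nodes:
                tol = 3 * sd[x] / np.sqrt(1000)
                assert abs(d[x] - mean[x]) <= max(tol, 1e-12)

    def test_fixed_seed_bit_reproducible(self, triangle):
        a = epc(triangle, seed=42).scores
        b = epc(triangle, seed=42).scores
        assert (a == b).all()

    def test_raw_variant_is_monotone_rescaling(self, triangle):
        norm = epc(triangle, n_reduced=200, seed=3).scores
        raw = epc(triangle, n_reduced=200, seed=3, normalized=False).scores
        np.testing.assert_allclose(raw.to_numpy(), norm.to_numpy() * 200)

    def test_standard_error_shrinks_with_replicates(self, two_nodes_one_edge):
        """Across seeds, SE of the node score scales roughly as 1/sqrt(K)."""
        def spread(k):
            vals = [
                as_dict(epc(two_nodes_one_edge, n_reduced=k, seed=s))[0]
                for s in range(30)
            ]
            return np.std(vals)

        s_small, s_big = spread(50), spread(800)
        assert s_big < s_small / 2.5  # expected ratio 4

    def test_threshold_out_of_range_rejected(self, triangle):
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                epc(triangle, threshold=bad)


ALL_ALGORITHMS = list(INTEGRATION_ALGORITHMS) + list(COMPARISON_ALGORITHMS)


def run_by_name(name, G):
    fn = {**INTEGRATION_ALGORITHMS, **COMPARISON_ALGORITHMS}[name]
    return fn(G, seed=0) if name == "epc" else fn(G)


class TestStructuralProperties:
    @pytest.mark.parametrize("name", ALL_ALGORITHMS)
    @given(seed=st.integers(0, 10**6))
    def test_permutation_equivariance(self, name, seed):
        rng = np.random.default_rng(seed)
        G = random_connected_graph(7, 0.4, int(rng.integers(10**6)))
        perm = {i: f"n{j}" for i, j in enumerate(rng.permutation(len(G)))}
        H = nx.relabel_nodes(G, perm)
        a = as_dict(run_by_name(name, G))
        b = as_dict(run_by_name(name, H))
        relabeled = {perm[x]: v for x, v in a.items()}
        if name == "epc":  # Monte Carlo: equal in distribution, compare coarsely
            assert set(relabeled) == set(b)
            assert np.allclose(
                sorted(relabeled.values()), sorted(b.values()), atol=0.1
            )
        else:
            assert relabeled == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("name", ALL_ALGORITHMS)
    @pytest.mark.parametrize("G", [nx.cycle_graph(6), nx.complete_graph(5)],
                             ids=["C6", "K5"])
    def test_vertex_transitive_graphs_score_uniformly(self, name, G):
        scores = list(as_dict(run_by_name(name, G)).values())
        if name == "epc":
            assert max(scores) - min(scores) <= 0.1
        else:
            assert max(scores) - min(scores) <= 1e-9

    def test_parameters_recorded(self, triangle):
        t = epc(triangle, threshold=0.5, n_reduced=100, seed=9)
        assert t.params == {
            "threshold": 0.5, "n_reduced": 100, "rng_seed": 9, "normalized": True,
        }
        assert katz(triangle, alpha=0.2).params == {"alpha": 0.2}
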