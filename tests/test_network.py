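"""Network construction, topology, modularity and node roles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import soilnet as sn

from conftest import make_net, make_otu, random_graph


class TestFilterDominant:
    def test_low_prevalence_dropped(self):
        counts = np.ones((10, 2), dtype=int) * 50
        counts[1:, 1] = 0  # OTU2 present in 1/10 samples
        otu = make_otu(counts)
        kept = sn.filter_dominant(otu, min_mean_rel_abund=0.0,
                                  min_prevalence=0.3)
        assert kept.otu_ids == ["OTU1"]

    def test_everything_above_thresholds_is_identity(self):
        rng = np.random.default_rng(0)
        otu = make_otu(rng.integers(10, 60, size=(6, 8)))
        kept = sn.filter_dominant(otu, 0.001, 0.5)
        assert kept.otu_ids == otu.otu_ids

    def test_matches_exhaustive_check(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 20, size=(9, 6))
        counts[:, 0] = 0
        counts[0, 0] = 1
        otu = make_otu(counts)
        thr_a, thr_p = 0.02, 1 / 3
        kept = sn.filter_dominant(otu, thr_a, thr_p).otu_ids
        rel = otu.relative_abundance()
        expected = [o for o in otu.otu_ids
                    if rel[o].mean() >= thr_a
                    and (otu.counts[o] > 0).mean() >= thr_p]
        assert kept == expected

    def test_empty_result_is_an_error(self):
        otu = make_otu([[1, 1], [1, 1], [1, 1]])
        with pytest.raises(sn.ValidationError, match="relax"):
            sn.filter_dominant(otu, min_mean_rel_abund=0.99)


class TestCorrelationMatrix:
    def test_duplicated_otu_column_r_one(self):
        rng = np.random.default_rng(2)
        base = rng.integers(1, 50, size=6)
        counts = np.column_stack([base, base, rng.integers(1, 50, size=6)])
        r, p = sn.correlation_matrix(make_otu(counts), "pearson")
        assert r.iloc[0, 1] == pytest.approx(1.0)
        assert p.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_independent_otus_mean_r_near_zero(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(50, size=(100, 30))
        r, _ = sn.correlation_matrix(make_otu(counts), "spearman")
        off = r.to_numpy()[np.triu_indices(30, 1)]
        assert abs(off.mean()) < 0.05

    def test_hand_spearman_pair(self):
        counts = np.column_stack([[1, 2, 3, 4, 5], [2, 1, 4, 3, 5]])
        # pad with a constant-total third OTU so compositions stay monotone
        counts = np.column_stack([counts, 100 - counts.sum(axis=1)])
        r, p = sn.correlation_matrix(make_otu(counts), "spearman")
        # d^2 = (1,1,1,1,0): rho = 1 - 6*4/(5*24) = 0.8
        assert r.iloc[0, 1] == pytest.approx(0.8)
        from scipy import stats
        r_ref, p_ref = stats.spearmanr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r.iloc[0, 1] == pytest.approx(r_ref)
        assert p.iloc[0, 1] == pytest.approx(p_ref)

    def test_constant_otu_gives_nan(self):
        counts = np.column_stack([[5, 5, 5, 5, 5],
                                  [1, 2, 3, 4, 5],
                                  [5, 4, 3, 2, 1]])
        # constant composition for OTU1 after closure requires constant depth
        r, _ = sn.correlation_matrix(make_otu(counts + 0), "spearman")
        assert np.isnan(r.iloc[0, 1])

    def test_refuses_tiny_n(self):
        with pytest.raises(sn.ValidationError, match="at least 5"):
            sn.correlation_matrix(make_otu([[1, 2], [3, 4], [5, 6],
                                            [7, 8]]), "spearman")


class TestBuildNetwork:
    @staticmethod
    def _mats(r, p=None):
        ids = [f"o{i}" for i in range(r.shape[0])]
        rdf = pd.DataFrame(r, index=ids, columns=ids)
        pdf = pd.DataFrame(np.zeros_like(r) if p is None else p,
                           index=ids, columns=ids)
        return rdf, pdf

    def test_no_thresholds_gives_complete_graph(self):
        r, p = self._mats(np.ones((4, 4)))
        net = sn.build_network(r, p, r_min=0.0, p_max=1.0, adjust="none")
        assert net.n_nodes == 4 and net.n_edges == 6

    def test_unreachable_threshold_gives_empty_network(self):
        r, p = self._mats(np.ones((4, 4)) * 0.9)
        with pytest.warns(UserWarning, match="no edge"):
            net = sn.build_network(r, p, r_min=1.01, p_max=0.05,
                                   adjust="none")
        assert net.n_edges == 0

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(4)
        r = rng.uniform(-1, 1, size=(5, 5))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        p = rng.uniform(0, 0.2, size=(5, 5))
        p = (p + p.T) / 2
        rdf, pdf = self._mats(r, p)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            net = sn.build_network(rdf, pdf, r_min=0.7, p_max=0.05,
                                   adjust="none", keep_isolated=True)
        expected = {(f"o{i}", f"o{j}")
                    for i, j in itertools.combinations(range(5), 2)
                    if abs(r[i, j]) >= 0.7 and p[i, j] <= 0.05}
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == expected

    def test_edge_criterion_is_monotone(self):
        rng = np.random.default_rng(5)
        r = rng.uniform(-1, 1, size=(8, 8))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        p = rng.uniform(0, 0.3, size=(8, 8))
        p = (p + p.T) / 2
        rdf, pdf = self._mats(r, p)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loose = sn.build_network(rdf, pdf, 0.3, 0.2, adjust="none")
            tight_r = sn.build_network(rdf, pdf, 0.6, 0.2, adjust="none")
            tight_p = sn.build_network(rdf, pdf, 0.3, 0.05, adjust="none")
        loose_edges = {tuple(sorted(e)) for e in loose.graph.edges}
        for tighter in (tight_r, tight_p):
            assert {tuple(sorted(e)) for e in tighter.graph.edges} <= loose_edges

    def test_sign_attribute_tracks_correlation_sign(self):
        r = np.array([[1.0, -0.9], [-0.9, 1.0]])
        rdf, pdf = self._mats(r)
        net = sn.build_network(rdf, pdf, 0.7, 0.05, adjust="none")
        assert net.graph.edges["o0", "o1"]["sign"] == -1


class TestTopology:
    def test_triangle(self, triangle):
        t = sn.topology(triangle)
        assert t["density"] == pytest.approx(1.0)
        assert t["clustering"] == pytest.approx(1.0)
        assert t["path_length"] == pytest.approx(1.0)
        assert t["mean_degree"] == pytest.approx(2.0)

    def test_path_graph_hand_enumeration(self):
        p4 = make_net([(0, 1), (1, 2), (2, 3)])
        t = sn.topology(p4)
        assert t["density"] == pytest.approx(0.5)
        assert t["mean_degree"] == pytest.approx(1.5)
        assert t["path_length"] == pytest.approx(10 / 6)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            net = random_graph(rng)
            t = sn.topology(net)
            adj = net.adjacency()
            n = adj.shape[0]
            e = adj.sum() / 2
            assert t["nodes"] == n and t["edges"] == e
            assert t["density"] == pytest.approx(2 * e / (n * (n - 1)))
            assert t["mean_degree"] == pytest.approx(2 * e / n)
            # Floyd-Warshall on the largest component
            dist = np.where(adj > 0, 1.0, np.inf)
            np.fill_diagonal(dist, 0.0)
            for k in range(n):
                dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
            comp_sizes = {}
            comp = max(nx.connected_components(net.graph), key=len)
            idx = [i for i, node in enumerate(net.graph.nodes) if node in comp]
            if len(idx) > 1:
                sub = dist[np.ix_(idx, idx)]
                ref_cpl = sub[sub > 0].mean()
                assert t["path_length"] == pytest.approx(ref_cpl, abs=1e-9)
            # direct triangle-counting clustering
            locals_ = []
            for i in range(n):
                nbrs = np.flatnonzero(adj[i])
                k = len(nbrs)
                if k < 2:
                    locals_.append(0.0)
                    continue
                tri = adj[np.ix_(nbrs, nbrs)].sum() / 2
                locals_.append(2 * tri / (k * (k - 1)))
            assert t["clustering"] == pytest.approx(np.mean(locals_), abs=1e-9)


class TestModularity:
    def test_two_disjoint_triangles_q_half(self, two_triangles):
        assignment, q = sn.detect_modules(two_triangles)
        assert q == pytest.approx(0.5)
        assert len(set(assignment.values())) == 2

    def test_single_module_q_zero(self, two_triangles):
        q = sn.modularity(two_triangles,
                          {n: 0 for n in two_triangles.graph.nodes})
        assert q == pytest.approx(0.0)

    def test_planted_partition_recovered(self):
        from sklearn.metrics import rand_score
        net = sn.planted_partition_graph(4, 20, 0.9, 0.05, seed=0)
        assignment, q = sn.detect_modules(net)
        truth = [net.graph.nodes[n]["true_block"] for n in net.graph.nodes]
        pred = [assignment[n] for n in net.graph.nodes]
        assert rand_score(truth, pred) > 0.9
        assert q > 0.3

    def test_detected_partition_beats_trivial_partitions(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            net = random_graph(rng, n_max=30, p=0.2)
            if net.n_edges == 0:
                continue
            assignment, q = sn.detect_modules(net)
            nodes = list(net.graph.nodes)
            q_single = sn.modularity(net, {n: 0 for n in nodes})
            q_singletons = sn.modularity(net, {n: i for i, n in enumerate(nodes)})
            assert q >= q_single - 1e-12
            assert q >= q_singletons - 1e-12

    def test_detection_is_deterministic(self):
        net = sn.planted_partition_graph(3, 10, 0.8, 0.1, seed=1)
        a1, q1 = sn.detect_modules(net)
        a2, q2 = sn.detect_modules(net)
        assert a1 == a2 and q1 == q2


class TestZiPi:
    def test_all_edges_inside_module_pi_zero(self, two_triangles):
        sn.detect_modules(two_triangles)
        roles = sn.zi_pi(two_triangles)
        assert (roles["pi"] == 0).all()

    def test_even_split_across_two_modules_pi_half(self):
        net = make_net([("c", f"m1_{i}") for i in range(2)]
                       + [("c", f"m2_{i}") for i in range(2)]
                       + [("m1_0", "m1_1"), ("m2_0", "m2_1")])
        modules = {"c": 0, "m1_0": 0, "m1_1": 0, "m2_0": 1, "m2_1": 1}
        net.set_modules(modules)
        roles = sn.zi_pi(net)
        assert roles.loc["c", "pi"] == pytest.approx(0.5)

    def test_zi_zero_when_within_degree_equals_module_mean(self, triangle):
        triangle.set_modules({n: 0 for n in triangle.graph.nodes})
        roles = sn.zi_pi(triangle)
        assert (roles["zi"] == 0).all()   # symmetric: sd=0 convention

    def test_isolated_node_flagged_peripheral(self):
        net = make_net([(0, 1)], nodes=[0, 1, 2])
        net.set_modules({0: 0, 1: 0, 2: 1})
        roles = sn.zi_pi(net)
        assert roles.loc[2, "role"] == "peripheral"
        assert roles.loc[2, "isolated"]
        assert np.isnan(roles.loc[2, "pi"])

    def test_roles_invariant_to_module_relabeling(self):
        net = sn.planted_partition_graph(3, 8, 0.9, 0.1, seed=3)
        assignment, _ = sn.detect_modules(net)
        roles1 = sn.zi_pi(net, assignment)
        relabeled = {n: 100 - m for n, m in assignment.items()}
        roles2 = sn.zi_pi(net, relabeled)
        pd.testing.assert_series_equal(roles1["role"], roles2["role"])
        pd.testing.assert_series_equal(roles1["zi"], roles2["zi"])
        pd.testing.assert_series_equal(roles1["pi"], roles2["pi"])

    def test_role_boundaries(self):
        # star centre linking many modules: high Pi, low Zi -> connector
        edges = [("hub", f"m{i}_a") for i in range(5)]
        edges += [(f"m{i}_a", f"m{i}_b") for i in range(5)]
        net = make_net(edges)
        modules = {"hub": 0}
        for i in range(5):
            modules[f"m{i}_a"] = i + 1
            modules[f"m{i}_b"] = i + 1
        net.set_modules(modules)
        roles = sn.zi_pi(net)
        assert roles.loc["hub", "role"] == "connector"
        assert roles.loc["hub", "pi"] == pytest.approx(0.8)
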