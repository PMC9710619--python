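"""Diffusion engine: weights, stability, trajectories, t50 extraction."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netdiffuse.diffusion import (
    EPSILON,
    DiffusionConfig,
    ExpressionMatrix,
    calibrate_weight_scale,
    compute_edge_weights,
    diffuse,
    extract_t50,
    normalize_expression,
    t50_feature_matrix,
)
from tests.conftest import build_network, dense_diffusion_reference


def expr_of(frame_dict, samples=("s1",), normalized=True):
    """ExpressionMatrix from {gene: value or list-per-sample}."""
    data = {
        g: (list(v) if np.ndim(v) else [v] * len(samples)) for g, v in frame_dict.items()
    }
    frame = pd.DataFrame(data, index=list(samples)).T
    return ExpressionMatrix(frame, normalized=normalized)


class TestNormalize:
    def test_global_max_scaling(self):
        raw = expr_of({"a": [100.0, 200.0], "b": [50.0, 0.0]}, ["s1", "s2"], normalized=False)
        out = normalize_expression(raw)
        assert out.normalized
        assert out.values.loc["a", "s2"] == 1.0
        assert out.values.loc["a", "s1"] == 0.5
        assert out.values.loc["b", "s2"] == EPSILON  # zero floored

    def test_all_zero_row_floored(self):
        raw = expr_of({"a": 10.0, "b": 0.0}, normalized=False)
        assert normalize_expression(raw).values.loc["b", "s1"] == EPSILON

    def test_negative_rejected(self):
        raw = expr_of({"a": 1.0, "b": -1.2}, normalized=False)
        with pytest.raises(ValueError, match="negative"):
            normalize_expression(raw)

    def test_idempotent(self):
        raw = expr_of({"a": [3.0, 7.0], "b": [1.0, 2.0]}, ["s1", "s2"], normalized=False)
        once = normalize_expression(raw)
        twice = normalize_expression(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestCalibrate:
    def test_two_node_closed_form(self, two_node):
        net, _ = two_node
        alpha = calibrate_weight_scale(expr_of({"A": 1.0, "B": 1.0}), net)
        assert alpha == pytest.approx(np.sqrt(0.5), abs=1e-12)
        # scaled weighted degree exactly 0.5
        w = compute_edge_weights(expr_of({"A": 1.0, "B": 1.0}), "s1", net, alpha)
        assert w.weighted_degree().max() == pytest.approx(0.5, abs=1e-12)

    def test_capped_at_one_for_tiny_expression(self, two_node):
        net, _ = two_node
        assert calibrate_weight_scale(expr_of({"A": 0.2, "B": 0.5}), net) == 1.0

    @pytest.mark.parametrize("k", [3, 8])
    def test_star_closed_form(self, k):
        leaves = [f"L{i}" for i in range(k)]
        net, _ = build_network(
            [("HUB", leaf) for leaf in leaves],
            receptors=["HUB"], tfs=leaves[:1], transducers=leaves[1:] or ["X"],
        )
        expr = expr_of({g: 1.0 for g in ["HUB", *leaves]})
        assert calibrate_weight_scale(expr, net) == pytest.approx(np.sqrt(0.5 / k))


class TestEdgeWeights:
    def test_product_rule(self, two_node):
        net, _ = two_node
        w = compute_edge_weights(expr_of({"A": 0.5, "B": 0.5}), "s1", net, alpha=1.0)
        assert w.matrix[0, 1] == pytest.approx(0.25)
        assert w.matrix[1, 0] == pytest.approx(0.25)

    def test_floor_keeps_edges_alive(self, two_node):
        net, _ = two_node
        w = compute_edge_weights(expr_of({"A": EPSILON, "B": 0.5}), "s1", net, alpha=1.0)
        assert 0 < w.matrix[0, 1] == pytest.approx(EPSILON * 0.5)

    def test_matches_dense_outer_product_oracle(self):
        rng = np.random.default_rng(11)
        g = nx.gnp_random_graph(12, 0.4, seed=2)
        names = [f"N{i:02d}" for i in range(12)]
        edges = [(names[a], names[b]) for a, b in g.edges()]
        net, _ = build_network(edges, receptors=names[:1], tfs=names[1:2], transducers=names[2:])
        e = {g_: rng.uniform(0.1, 1.0) for g_ in net.nodes}
        expr = expr_of(e)
        alpha = calibrate_weight_scale(expr, net)
        w = compute_edge_weights(expr, "s1", net, alpha).matrix.toarray()
        vec = np.array([alpha * e[g_] for g_ in net.nodes])
        adj = nx.to_numpy_array(net.graph, nodelist=net.nodes)
        assert np.allclose(w, adj * np.outer(vec, vec), atol=1e-14)

    def test_missing_gene_listed(self, two_node):
        net, _ = two_node
        with pytest.raises(ValueError, match=r"\['B'\]"):
            compute_edge_weights(expr_of({"A": 0.5}), "s1", net, alpha=1.0)

    def test_stability_violation_names_node(self, two_node):
        net, _ = two_node
        with pytest.raises(ValueError, match="stability bound"):
            compute_edge_weights(expr_of({"A": 1.0, "B": 1.0}), "s1", net, alpha=1.0)


class TestDiffuse:
    def _weights(self, net, e, alpha=1.0):
        return compute_edge_weights(expr_of(e), "s1", net, alpha)

    def test_two_node_closed_form(self, two_node):
        net, _ = two_node
        w = self._weights(net, {"A": 0.5, "B": 0.5})  # w = 0.25
        traj = diffuse(net, w, DiffusionConfig(horizon=50, source="A", monitored=("B",)))
        t = np.arange(51)
        expected = (1.0 - (1.0 - 2 * 0.25) ** t) / 2.0
        assert np.abs(traj["B"].to_numpy() - expected).max() < 1e-12
        assert traj["B"].iloc[1] == pytest.approx(0.25)
        assert traj["B"].iloc[2] == pytest.approx(0.375)

    def test_disconnected_tf_stays_zero(self):
        net, _ = build_network(
            [("R1", "K1"), ("T2", "K2")],
            receptors=["R1"], tfs=["T2"], transducers=["K1", "K2"],
        )
        w = self._weights(net, {"R1": 0.5, "K1": 0.5, "T2": 0.5, "K2": 0.5})
        traj = diffuse(net, w, DiffusionConfig(horizon=100, source="R1", monitored=("T2",)))
        assert (traj["T2"] == 0).all()

    def test_source_absent_errors(self, two_node):
        net, _ = two_node
        w = self._weights(net, {"A": 0.5, "B": 0.5})
        with pytest.raises(ValueError, match="source"):
            diffuse(net, w, DiffusionConfig(horizon=5, source="Q", monitored=("B",)))

    def test_conservation_and_nonnegativity_random_graphs(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 16))
            g = nx.gnp_random_graph(n, 0.5, seed=seed)
            if g.number_of_edges() == 0:
                continue
            names = [f"N{i:02d}" for i in range(n)]
            edges = [(names[a], names[b]) for a, b in g.edges()]
            net, _ = build_network(edges, receptors=names[:1], tfs=names[1:2],
                                   transducers=names[2:] or ["X"])
            e = {g_: rng.uniform(0.05, 1.0) for g_ in net.nodes}
            expr = expr_of(e)
            alpha = calibrate_weight_scale(expr, net)
            w = compute_edge_weights(expr, "s1", net, alpha)
            traj = diffuse(net, w, DiffusionConfig(horizon=300, source=net.nodes[0],
                                                   monitored=tuple(net.nodes)))
            totals = traj.sum(axis=1).to_numpy()
            assert np.abs(totals - 1.0).max() < 1e-9
            assert traj.to_numpy().min() >= -1e-12

    def test_matches_dense_flux_reference(self):
        for seed in [0, 1, 2]:
            rng = np.random.default_rng(seed)
            n = 9
            g = nx.gnp_random_graph(n, 0.5, seed=seed + 50)
            names = [f"N{i}" for i in range(n)]
            edges = [(names[a], names[b]) for a, b in g.edges()]
            if not edges:
                continue
            net, _ = build_network(edges, receptors=names[:1], tfs=names[1:2],
                                   transducers=names[2:])
            e = {g_: rng.uniform(0.1, 1.0) for g_ in net.nodes}
            expr = expr_of(e)
            alpha = calibrate_weight_scale(expr, net)
            w = compute_edge_weights(expr, "s1", net, alpha)
            traj = diffuse(net, w, DiffusionConfig(horizon=200, source=net.nodes[0],
                                                   monitored=tuple(net.nodes)))
            weight = {
                (a, b): float(w.matrix[net.node_index[a], net.node_index[b]])
                for a, b in net.edges()
            }
            ref = dense_diffusion_reference(net.nodes, weight, net.nodes[0], 200)
            assert np.abs(traj.to_numpy() - ref).max() < 1e-10

    def test_convergence_to_uniform(self):
        # connected graph, every weight >= 0.01 -> equilibrium 1/N by 2000 steps
        n = 8
        g = nx.connected_watts_strogatz_graph(n, 4, 0.3, seed=1)
        names = [f"N{i}" for i in range(n)]
        edges = [(names[a], names[b]) for a, b in g.edges()]
        net, _ = build_network(edges, receptors=names[:1], tfs=names[1:2], transducers=names[2:])
        expr = expr_of({g_: 1.0 for g_ in net.nodes})
        alpha = calibrate_weight_scale(expr, net)
        w = compute_edge_weights(expr, "s1", net, alpha)
        assert w.matrix.data.min() >= 0.01
        traj = diffuse(net, w, DiffusionConfig(horizon=2000, source=net.nodes[0],
                                               monitored=tuple(net.nodes)))
        assert np.abs(traj.iloc[-1].to_numpy() - 1.0 / net.n_nodes).max() < 1e-3


class TestExtractT50:
    def test_fast_edge(self, two_node):
        net, _ = two_node
        w = compute_edge_weights(expr_of({"A": 0.5, "B": 0.5}), "s1", net, 1.0)
        traj = diffuse(net, w, DiffusionConfig(horizon=2000, source="A", monitored=("B",)))
        assert extract_t50(traj["B"], DiffusionConfig()) == 1.0

    def test_slow_edge_closed_form(self, two_node):
        # w = 0.01: smallest t with (1 - 0.98^t)/2 >= 0.5 * max -> 35
        net, _ = two_node
        w = compute_edge_weights(expr_of({"A": 0.1, "B": 0.1}), "s1", net, 1.0)
        assert w.matrix[0, 1] == pytest.approx(0.01)
        traj = diffuse(net, w, DiffusionConfig(horizon=2000, source="A", monitored=("B",)))
        t50 = extract_t50(traj["B"], DiffusionConfig())
        assert t50 == 35.0
        # brute-force scalar recurrence agrees
        s, level, target = 0.0, [], None
        for t in range(2001):
            level.append(s)
            s = s + (1 - 2 * s) * 0.01
        m = max(level)
        brute = next(t for t, v in enumerate(level) if v >= 0.5 * m)
        assert brute == 35

    def test_zero_trajectory_missing(self):
        assert np.isnan(extract_t50(np.zeros(100), DiffusionConfig()))


class TestT50FeatureMatrix:
    def _toy(self, n_samples=4):
        edges = [("R1", "K1"), ("R2", "K1"), ("K1", "T1"), ("K1", "T2"), ("K1", "T3")]
        net, roles = build_network(edges, receptors=["R1", "R2"],
                                   tfs=["T1", "T2", "T3"], transducers=["K1"])
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(n_samples)]
        frame = pd.DataFrame(
            rng.uniform(0.2, 1.0, size=(len(net.nodes), n_samples)),
            index=net.nodes, columns=samples,
        )
        return net, roles, ExpressionMatrix(frame, normalized=True)

    def test_dimension_contract(self):
        net, roles, expr = self._toy()
        t50 = t50_feature_matrix(expr, net, roles, DiffusionConfig(horizon=500))
        assert t50.values.shape == (4, 6)
        assert list(t50.values.columns.names) == ["receptor", "tf"]
        # receptor-major, lexicographic
        assert list(t50.values.columns[:3]) == [("R1", "T1"), ("R1", "T2"), ("R1", "T3")]

    def test_sample_permutation_invariance(self):
        net, roles, expr = self._toy()
        t50 = t50_feature_matrix(expr, net, roles, DiffusionConfig(horizon=500))
        shuffled = ExpressionMatrix(expr.values[["s2", "s0", "s3", "s1"]], normalized=True)
        t50_shuf = t50_feature_matrix(shuffled, net, roles, DiffusionConfig(horizon=500))
        pd.testing.assert_frame_equal(t50.values.loc[t50_shuf.values.index], t50_shuf.values)

    def test_scale_comparability(self):
        net, roles, _ = self._toy()
        rng = np.random.default_rng(8)
        raw = pd.DataFrame(rng.uniform(1, 100, size=(len(net.nodes), 3)),
                           index=net.nodes, columns=["a", "b", "c"])
        t50_a = t50_feature_matrix(ExpressionMatrix(raw), net, roles, DiffusionConfig(horizon=500))
        t50_b = t50_feature_matrix(ExpressionMatrix(raw * 37.5), net, roles,
                                   DiffusionConfig(horizon=500))
        pd.testing.assert_frame_equal(t50_a.values, t50_b.values)
        assert t50_a.alpha == pytest.approx(t50_b.alpha)

    def test_monotone_connectivity_in_transducer_expression(self, chain_network):
        # weaker transducer expression -> strictly slower receptor-TF connectivity
        net, roles = chain_network
        grid = [0.9, 0.7, 0.5, 0.3, 0.15, 0.08]
        samples = [f"e{i}" for i in range(len(grid))]
        frame = pd.DataFrame(
            {s: [1.0, ek, 1.0] for s, ek in zip(samples, grid)},
            index=["R1", "K1", "T1"],
        ).loc[net.nodes]
        expr = ExpressionMatrix(frame, normalized=True)
        t50 = t50_feature_matrix(expr, net, roles, DiffusionConfig(horizon=2000))
        series = t50.values[("R1", "T1")].to_numpy()
        assert (np.diff(series) > 0).all()

    def test_missing_pairs_are_nan(self):
        edges = [("R1", "K1"), ("K1", "T1"), ("R2", "K2"), ("K2", "T2")]
        net, roles = build_network(edges, receptors=["R1", "R2"], tfs=["T1", "T2"],
                                   transducers=["K1", "K2"])
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [0.5] * 6},
                         index=["R1", "R2", "K1", "K2", "T1", "T2"]).loc[net.nodes],
            normalized=True,
        )
        t50 = t50_feature_matrix(expr, net, roles, DiffusionConfig(horizon=200))
        assert np.isnan(t50.values.loc["s1", ("R1", "T2")])
        assert np.isfinite(t50.values.loc["s1", ("R1", "T1")])
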