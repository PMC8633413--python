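"""Network inference: smoothing, regulator selection, ODE decomposition,
edges and degree tables."""

import numpy as np
import pytest

from crinet.errors import InvalidInputError
from crinet.network import (build_layer_network, deconstruct_node_effect,
                            degree_distribution, edge_from_decomposition,
                            fit_ode_decomposition, select_regulators,
                            smooth_and_interpolate)
from crinet.simulate import (NETWORK_FIXTURE_TIMES, _random_smooth_curves,
                             simulate_network_system)


def _smooth_set(curves, times, order=12):
    return {f"node{i}": smooth_and_interpolate(f"node{i}", curves[i], times,
                                               order=order)
            for i in range(curves.shape[0])}


class TestSmoothing:
    def test_polynomial_reproduced_exactly(self, annual_times):
        y = 1.0 + 0.5 * annual_times - 0.1 * annual_times ** 2
        s = smooth_and_interpolate("n", y, annual_times, order=2)
        assert s.rmse < 1e-10
        dense_truth = 1.0 + 0.5 * s.dense_times - 0.1 * s.dense_times ** 2
        assert np.abs(s.dense_values - dense_truth).max() < 1e-10

    def test_constant_curve_zero_derivative(self, annual_times):
        s = smooth_and_interpolate("n", np.full(14, 3.0), annual_times, order=3)
        assert np.abs(s.dense_deriv).max() < 1e-10

    def test_derivative_matches_finite_differences(self, annual_times):
        y = np.sin(annual_times / 3.0)
        s = smooth_and_interpolate("n", y, annual_times, order=8, n_dense=400)
        fd = np.gradient(s.dense_values, s.dense_times)
        # interior points only; central differences are O(grid^2)
        assert np.abs(s.dense_deriv[5:-5] - fd[5:-5]).max() < 1e-3

    def test_order_at_least_npoints_rejected(self):
        with pytest.raises(InvalidInputError):
            smooth_and_interpolate("n", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                   order=3)


class TestSelection:
    def test_proportional_curve_found_among_decoys(self):
        """Static screen: a focal curve exactly 2x one candidate is pinned
        to that candidate with a positive coefficient."""
        t = NETWORK_FIXTURE_TIMES
        rng = np.random.default_rng(0)
        decoys = _random_smooth_curves(rng, 20, t, order=9)
        target = _random_smooth_curves(rng, 1, t, order=9)[0]
        focal_curve = 2.0 * target
        sm = {"focal": smooth_and_interpolate("focal", focal_curve, t, order=12),
              "target": smooth_and_interpolate("target", target, t, order=12)}
        cands = [sm["target"]] + [
            smooth_and_interpolate(f"decoy{i}", decoys[i], t, order=12)
            for i in range(20)]
        spec = select_regulators(sm["focal"], cands, target="value")
        assert spec.support == ["target"]
        assert spec.coefficients["target"] > 0

    def test_support_never_contains_focal(self):
        curves, _, t = simulate_network_system(seed=3)
        sm = _smooth_set(curves, t)
        for nid, focal in sm.items():
            spec = select_regulators(focal, list(sm.values()))
            assert nid not in spec.support

    def test_in_degree_cap_zero_gives_empty_support(self):
        curves, _, t = simulate_network_system(seed=4)
        sm = _smooth_set(curves, t)
        spec = select_regulators(sm["node3"], list(sm.values()),
                                 max_in_degree=0)
        assert spec.support == []

    def test_constant_candidates_give_empty_support(self):
        t = NETWORK_FIXTURE_TIMES
        focal = smooth_and_interpolate("f", np.sin(t), t, order=8)
        flat = [smooth_and_interpolate(f"c{i}", np.full(t.size, float(i)), t,
                                       order=2) for i in range(3)]
        spec = select_regulators(focal, flat)
        assert spec.support == []

    def test_needs_candidates(self):
        t = NETWORK_FIXTURE_TIMES
        focal = smooth_and_interpolate("f", np.sin(t), t, order=8)
        with pytest.raises(InvalidInputError):
            select_regulators(focal, [focal])


class TestDecomposition:
    def test_empty_regulator_set_pure_independent(self):
        curves, _, t = simulate_network_system(seed=5)
        sm = _smooth_set(curves, t)
        spec = select_regulators(sm["node0"], list(sm.values()),
                                 max_in_degree=0)
        dec = fit_ode_decomposition(sm["node0"], spec, sm)
        assert dec.regulators == []
        assert np.allclose(dec.independent_deriv, sm["node0"].dense_deriv)
        assert dec.dependent_derivs == {}

    def test_constructed_truth_linear_coupling(self):
        """Focal derivative = own logistic-like term + 0.5 * regulator curve:
        the fitted dependent component recovers the planted half-strength
        regulator term."""
        t = np.linspace(1.0, 15.0, 30)
        # the regulator oscillates faster than anything a low-order function
        # of the monotone focal state can mimic, so the split is identifiable
        reg_vals = 2.0 + np.sin(t) + 0.1 * t
        own = 0.3 * t * np.exp(-t / 6.0)
        focal_deriv = own + 0.5 * reg_vals
        focal_vals = 1.0 + np.concatenate(
            [[0.0], np.cumsum(0.5 * (focal_deriv[1:] + focal_deriv[:-1])
                              * np.diff(t))])
        sm = {"reg": smooth_and_interpolate("reg", reg_vals, t, order=12),
              "focal": smooth_and_interpolate("focal", focal_vals, t, order=12)}
        spec = select_regulators(sm["focal"], [sm["reg"]])
        assert spec.support == ["reg"]
        dec = fit_ode_decomposition(sm["focal"], spec, sm)
        planted = 0.5 * np.interp(dec.dense_times, t, reg_vals)
        # the constant part of any component is attributed to the
        # independent term, so compare the identifiable (centred) parts
        got = dec.dependent_derivs["reg"] - dec.dependent_derivs["reg"].mean()
        want = planted - planted.mean()
        rmse = np.sqrt(np.mean((got - want) ** 2))
        assert rmse < 0.05 * np.sqrt(np.mean(want ** 2))

    def test_conservation_at_every_grid_point(self):
        curves, _, t = simulate_network_system(seed=6)
        sm = _smooth_set(curves, t)
        for nid, focal in sm.items():
            spec = select_regulators(focal, list(sm.values()))
            dec = fit_ode_decomposition(focal, spec, sm)
            total = dec.independent_deriv + sum(dec.dependent_derivs.values())
            scale = np.abs(focal.dense_deriv).max()
            assert np.abs(total - focal.dense_deriv).max() < 1e-6 * max(scale, 1)

    def test_rk4_reconstruction_tracks_curve(self):
        curves, _, t = simulate_network_system(seed=7)
        sm = _smooth_set(curves, t)
        focal = sm["node3"]
        spec = select_regulators(focal, list(sm.values()))
        dec = fit_ode_decomposition(focal, spec, sm)
        scale = np.sqrt(np.mean((focal.dense_values - focal.dense_values.mean()) ** 2))
        assert dec.reconstruction_rmse < 0.02 * max(scale, 1e-12)


class TestEdges:
    def test_zero_component_no_edge(self):
        curves, _, t = simulate_network_system(seed=8)
        sm = _smooth_set(curves, t)
        spec = select_regulators(sm["node0"], list(sm.values()),
                                 max_in_degree=0)
        dec = fit_ode_decomposition(sm["node0"], spec, sm)
        assert edge_from_decomposition(dec) == []

    def test_sign_flips_with_regulator_sign_weight_preserved(self):
        t = np.linspace(1.0, 15.0, 30)
        reg_vals = 2.0 + np.sin(t) + 0.1 * t
        own = 0.3 * t * np.exp(-t / 6.0)
        edges = {}
        for c in (0.5, -0.5):
            focal_deriv = own + c * reg_vals
            vals = 1.0 + np.concatenate(
                [[0.0], np.cumsum(0.5 * (focal_deriv[1:] + focal_deriv[:-1])
                                  * np.diff(t))])
            sm = {"reg": smooth_and_interpolate("reg", reg_vals, t, order=12),
                  "focal": smooth_and_interpolate("focal", vals, t, order=12)}
            spec = select_regulators(sm["focal"], [sm["reg"]])
            dec = fit_ode_decomposition(sm["focal"], spec, sm)
            (edge,) = edge_from_decomposition(dec)
            edges[c] = edge
        assert edges[0.5].sign == 1 and edges[-0.5].sign == -1
        assert edges[0.5].weight == pytest.approx(edges[-0.5].weight, rel=0.05)


class TestLayerNetworks:
    def test_independent_curves_give_empty_network(self):
        rng = np.random.default_rng(9)
        t = NETWORK_FIXTURE_TIMES
        base = _random_smooth_curves(rng, 2, t, order=9)
        net = build_layer_network({"a": base[0], "b": base[1]}, t,
                                  trait="height", smooth_order=12)
        assert net.graph.number_of_edges() == 0

    def test_planted_two_layer_recovered_exactly(self):
        curves, true_edges, t = simulate_network_system(seed=0)
        nc = {f"node{i}": curves[i] for i in range(5)}
        net = build_layer_network(nc, t, trait="height", smooth_order=12,
                                  seed=0)
        found = {(u, v): d["sign"] for u, v, d in net.graph.edges(data=True)}
        truth = {(u, v): s for u, v, s in true_edges}
        assert found == truth

    def test_variant_plumbing(self):
        curves, _, t = simulate_network_system(seed=13)
        nc = {f"node{i}": curves[i] for i in range(5)}
        net = build_layer_network(nc, t, trait="diameter",
                                  variant="independent", layer="local",
                                  qtl_nodes={"node1"}, smooth_order=12)
        assert net.variant == "independent" and net.layer == "local"
        assert net.graph.nodes["node1"]["qtl"]
        assert not net.graph.nodes["node0"]["qtl"]

    def test_degree_tables(self):
        import networkx as nx
        from crinet.network import EpistaticNetwork
        g = nx.DiGraph()
        g.add_nodes_from("abc")
        g.add_edge("a", "b", sign=1, weight=1.0)
        g.add_edge("b", "c", sign=-1, weight=2.0)
        net = EpistaticNetwork("metagalactic", "height", "overall", g, {})
        per_node, out_hist, in_hist = degree_distribution(net)
        lookup = per_node.set_index("node")
        assert list(lookup.loc[["a", "b", "c"], "out_degree"]) == [1, 1, 0]
        assert list(lookup.loc[["a", "b", "c"], "in_degree"]) == [0, 1, 1]
        assert per_node["out_degree"].sum() == per_node["in_degree"].sum() == 2

    def test_deconstruction_report(self):
        curves, true_edges, t = simulate_network_system(seed=14)
        nc = {f"node{i}": curves[i] for i in range(5)}
        net = build_layer_network(nc, t, trait="height", smooth_order=12,
                                  seed=14)
        sinks = {v for _, v, _ in true_edges}
        sink = sorted(sinks)[0]
        dec = net.decompositions[sink]
        df = deconstruct_node_effect(dec)
        assert "net" in df and "independent" in df
        comps = df[[c for c in df.columns if c.startswith("dependent")]]
        # conservation on curves: independent + dependents ~ net up to a
        # common offset and the trapezoid quadrature error of the integrals
        resid = df["net"] - (df["independent"] + comps.sum(axis=1))
        assert np.abs(resid - resid.iloc[0]).max() < 0.02 * np.abs(df["net"]).max()

    def test_negative_regulation_puts_independent_above_net(self):
        curves, true_edges, t = simulate_network_system(seed=15)
        neg_sinks = {v for _, v, s in true_edges if s < 0}
        pos_sinks = {v for _, v, s in true_edges if s > 0}
        only_neg = sorted(neg_sinks - pos_sinks)
        if not only_neg:
            pytest.skip("seed produced no purely negatively regulated sink")
        nc = {f"node{i}": curves[i] for i in range(5)}
        net = build_layer_network(nc, t, trait="height", smooth_order=12)
        dec = net.decompositions[only_neg[0]]
        df = deconstruct_node_effect(dec)
        assert df["independent"].iloc[-1] > df["net"].iloc[-1]


class TestFixedSupport:
    def test_fixed_support_bypasses_selection(self):
        curves, true_edges, t = simulate_network_system(seed=16)
        nc = {f"node{i}": curves[i] for i in range(5)}
        support = {}
        for u, v, _ in true_edges:
            support.setdefault(v, []).append(u)
        for nid in nc:
            support.setdefault(nid, [])
        net = build_layer_network(nc, t, trait="height", smooth_order=12,
                                  fixed_support=support)
        found = set(net.graph.edges())
        truth = {(u, v) for u, v, _ in true_edges}
        assert found == truth
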