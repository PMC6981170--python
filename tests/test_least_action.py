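"""Discretized least-action paths: action values, gradients, minimization."""

import numpy as np
import pytest
from scipy.integrate import quad

import endonet as en
from endonet.landscape import LandscapeConfig, integrate_trajectory, unstable_perturbations
from endonet.least_action import (ENDOCRINE_CHAIN, MPPConfig, action,
                                  action_gradient, lineage_mpp_suite,
                                  minimize_action, refinement_check)


def toy_barrier():
    """Quadrature oracle: for a 1-D gradient system the uphill action from 0
    to the saddle 1/2 equals the integral of -f = x - H(x)."""
    H = lambda x: 16 * x ** 4 / (1 + 16 * x ** 4)
    val, _ = quad(lambda x: x - H(x), 0.0, 0.5)
    return val


class TestAction:
    def test_constant_path_at_equilibrium_is_free(self, pancreas, atlas):
        s = atlas.get("S1")
        path = np.tile(s.x, (11, 1))
        assert action(pancreas, path, atlas.params, dt=0.1) == 0.0

    def test_two_point_hand_evaluation(self, toy):
        # single segment x: 0 -> 0.1 with dt = 1:
        # S = 1/4 [0.1 - (f(0.1)+f(0))/2]^2, f(0)=0, f(0.1)=16e-4/1.0016-0.1
        net = toy["self_activator"].network
        f01 = 16 * 0.1 ** 4 / (1 + 16 * 0.1 ** 4) - 0.1
        expected = 0.25 * (0.1 - 0.5 * f01) ** 2
        got = action(net, np.array([[0.0], [0.1]]), en.HillParams(4), dt=1.0)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.005565, abs=1e-5)

    def test_flow_following_path_is_nearly_free(self, pancreas, atlas):
        s = atlas.by_class("transition")[0]
        start = unstable_perturbations(s, pancreas, atlas.params)[0]
        traj = integrate_trajectory(pancreas, start, atlas.params,
                                    LandscapeConfig(t_max=50.0), record_every=1)
        # resample onto a uniform N-point grid of the integration time
        n_pts = traj.shape[0]
        dt_traj = 0.01
        idx = np.linspace(0, n_pts - 1, 101).round().astype(int)
        path = traj[idx]
        dt = dt_traj * (n_pts - 1) / 100
        assert action(pancreas, path, atlas.params, dt=dt) < 1e-3

    def test_nonfinite_path_rejected(self, pancreas, atlas):
        path = np.zeros((3, 8))
        path[1, 0] = np.nan
        with pytest.raises(ValueError):
            action(pancreas, path, atlas.params, dt=0.1)

    def test_action_is_permutation_invariant(self, pancreas, atlas):
        from endonet.network import GeneNetwork, RegulatoryEdge

        rng = np.random.default_rng(0)
        path = rng.uniform(0, 1, (21, 8))
        perm = rng.permutation(8)
        edges = [RegulatoryEdge(e.source, e.target, e.sign) for e in pancreas.edges]
        net_p = GeneNetwork(edges, genes=[pancreas.genes[i] for i in perm])
        a = action(pancreas, path, atlas.params, dt=0.1)
        b = action(net_p, path[:, perm], atlas.params, dt=0.1)
        assert a == pytest.approx(b, rel=1e-12)


class TestGradient:
    def test_matches_finite_differences(self, pancreas, atlas):
        rng = np.random.default_rng(5)
        path = rng.uniform(0, 1, (8, 8))
        dt = 0.1
        grad = action_gradient(pancreas, path, atlas.params, dt)
        h = 1e-7
        for m in range(1, 7):
            for g in range(8):
                p1, p2 = path.copy(), path.copy()
                p1[m, g] += h
                p2[m, g] -= h
                fd = (action(pancreas, p1, atlas.params, dt=dt)
                      - action(pancreas, p2, atlas.params, dt=dt)) / (2 * h)
                assert grad[m - 1, g] == pytest.approx(fd, abs=1e-6)


class TestMinimize:
    def test_identical_endpoints_rejected(self, pancreas, atlas):
        s = atlas.get("S1")
        with pytest.raises(ValueError):
            minimize_action(pancreas, s.x, s.x, atlas.params)

    def test_downhill_saddle_to_attractor_is_nearly_free(self, pancreas, atlas, graph):
        s = atlas.by_class("transition")[0]
        target = next(v for v in graph.successors(s.label)
                      if atlas.get(v).classification == "stable")
        sol = minimize_action(pancreas, s.x, atlas.get(target).x, atlas.params)
        assert sol.action < 1e-3
        np.testing.assert_array_equal(sol.points[0], s.x)
        np.testing.assert_array_equal(sol.points[-1], atlas.get(target).x)

    def test_toy_uphill_action_converges_to_barrier(self, toy):
        net = toy["self_activator"].network
        sol = minimize_action(net, np.array([0.0]), np.array([0.5]),
                              en.HillParams(4), MPPConfig(T=40.0, N=400))
        assert sol.action == pytest.approx(toy_barrier(), abs=5e-3)

    def test_action_stable_under_grid_refinement(self, toy):
        """Refining N at fixed T changes the minimized action only at the
        level of the second-order discretization bias (the coarser
        trapezoidal functional slightly under-counts the barrier, so exact
        monotonicity in N does not hold)."""
        net = toy["self_activator"].network
        coarse = minimize_action(net, np.array([0.0]), np.array([0.5]),
                                 en.HillParams(4), MPPConfig(T=10.0, N=50))
        fine = minimize_action(net, np.array([0.0]), np.array([0.5]),
                               en.HillParams(4), MPPConfig(T=10.0, N=100))
        finer = minimize_action(net, np.array([0.0]), np.array([0.5]),
                                en.HillParams(4), MPPConfig(T=10.0, N=200))
        assert abs(fine.action - coarse.action) < 1e-3
        # second-order convergence: the N=100 -> 200 change is much smaller
        assert abs(finer.action - fine.action) < 0.5 * abs(fine.action - coarse.action)

    def test_reversed_downhill_path_costs_positive_action(self, toy):
        net = toy["self_activator"].network
        params = en.HillParams(4)
        down = minimize_action(net, np.array([0.5]), np.array([0.0]), params)
        assert down.action < 1e-4
        rev = action(net, down.points[::-1], params, dt=down.config.dt)
        assert rev > 0.05  # uphill costs roughly the barrier

    def test_warns_when_endpoint_not_an_equilibrium(self, pancreas, atlas):
        with pytest.warns(UserWarning, match="not an atlas equilibrium"):
            minimize_action(pancreas, atlas.get("S1").x, np.full(8, 0.3),
                            atlas.params, MPPConfig(N=10), atlas=atlas)


class TestRefinement:
    def test_identical_configs_give_zero_deviation(self, toy):
        net = toy["self_activator"].network
        cfg = MPPConfig(T=10.0, N=40)
        r = refinement_check(net, np.array([0.0]), np.array([0.5]),
                             en.HillParams(4), cfg, cfg)
        assert r["action_deviation"] == 0.0
        assert r["path_deviation"] == 0.0

    def test_toy_discretization_error_is_tiny(self, toy):
        net = toy["self_activator"].network
        r = refinement_check(net, np.array([0.0]), np.array([0.5]),
                             en.HillParams(4),
                             MPPConfig(T=10.0, N=100), MPPConfig(T=10.0, N=200))
        assert r["action_deviation"] < 1e-4

    def test_coarser_refinement_rejected(self, toy):
        net = toy["self_activator"].network
        with pytest.raises(ValueError):
            refinement_check(net, np.array([0.0]), np.array([0.5]),
                             en.HillParams(4), MPPConfig(N=100), MPPConfig(N=50))


class TestLineageSuite:
    def test_missing_stage_label_is_named(self, pancreas, atlas):
        with pytest.raises(KeyError, match="MP"):
            lineage_mpp_suite(pancreas, atlas, {"TrP": "S8"},
                              chains={"endocrine_beta": ("MP", "TrP")})

    def test_endocrine_chain_converges_with_clamped_endpoints(
            self, pancreas, atlas, cell_types):
        sols = lineage_mpp_suite(pancreas, atlas, cell_types,
                                 chains={"endocrine_beta": ENDOCRINE_CHAIN})
        segs = sols["endocrine_beta"]
        assert len(segs) == len(ENDOCRINE_CHAIN) - 1
        for seg, (a, b) in zip(segs, zip(ENDOCRINE_CHAIN[:-1], ENDOCRINE_CHAIN[1:])):
            assert seg.converged
            np.testing.assert_array_equal(seg.points[0], atlas.get(cell_types[a]).x)
            np.testing.assert_array_equal(seg.points[-1], atlas.get(cell_types[b]).x)

    def test_two_acinar_routes_have_distinct_interior_dynamics(
            self, pancreas, atlas, cell_types):
        sols = lineage_mpp_suite(
            pancreas, atlas, cell_types,
            chains={"via_AciP": ("TiP", "AciP", "acinar"),
                    "via_AciP2": ("TiP", "AciP2", "acinar")})
        p1 = np.vstack([s.points for s in sols["via_AciP"]])
        p2 = np.vstack([s.points for s in sols["via_AciP2"]])
        assert np.max(np.abs(p1 - p2)) > 0.1
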