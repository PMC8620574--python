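import numpy as np
import pytest

from perfusim import units
from perfusim.flow import (ConvergenceError, FlowConfigurationError,
                           boundary_node_flows, couple_flow, darcy_velocity,
                           edge_conductance, fluid_mass_balance, solve_ifp,
                           solve_vessel_pressure, starling_exchange,
                           vessel_weight_grid)
from perfusim.pipeline import bessel_ifp_benchmark, build_vasculature
from perfusim.types import (DomainSpec, TissueParams, VesselGraph,
                            normal_tissue_params, tumor_tissue_params)

from conftest import small_case_config

MU = 3e-3


class TestVesselPressure:
    def test_single_tube_linear_drop(self):
        r, L = 5e-6, 2e-3
        g = VesselGraph(
            np.array([[0.0, 0.0], [L / 2, 0.0], [L, 0.0]]),
            [(0, 1, r, L / 2), (1, 2, r, L / 2)],
            boundary_pressures={0: 3333.0, 2: 0.0},
        )
        p = solve_vessel_pressure(g, MU)
        assert p[1] == pytest.approx(1666.5)
        q_in = boundary_node_flows(g, p, MU)[0]
        assert q_in == pytest.approx(np.pi * r**4 * 3333.0 / (8 * MU * L))

    def test_symmetric_y_splits_flow_equally(self):
        r = 5e-6
        g = VesselGraph(
            np.array([[0.0, 0.0], [1e-3, 0.0], [2e-3, 5e-4], [2e-3, -5e-4]]),
            [(0, 1, r, 1e-3), (1, 2, r, 1.2e-3), (1, 3, r, 1.2e-3)],
            boundary_pressures={0: 100.0, 2: 0.0, 3: 0.0},
        )
        p = solve_vessel_pressure(g, MU)
        flows = boundary_node_flows(g, p, MU)
        assert flows[2] == pytest.approx(flows[3])
        assert flows[0] == pytest.approx(-(flows[2] + flows[3]))

    def test_random_network_mass_conservation(self, rng):
        n = 30
        pts = rng.uniform(0, 1e-2, size=(n, 2))
        edges = []
        for i in range(1, n):  # random tree
            j = int(rng.integers(0, i))
            d = float(np.hypot(*(pts[i] - pts[j]))) + 1e-6
            edges.append((j, i, float(rng.uniform(3e-6, 1e-5)), d))
        while len(edges) < 50:  # extra loops
            i, j = rng.integers(0, n, 2)
            if i == j:
                continue
            d = float(np.hypot(*(pts[i] - pts[j]))) + 1e-6
            edges.append((int(i), int(j), float(rng.uniform(3e-6, 1e-5)), d))
        g = VesselGraph(pts, edges,
                        boundary_pressures={0: 4000.0, 1: 500.0, 2: 0.0})
        p = solve_vessel_pressure(g, MU)
        flows = boundary_node_flows(g, p, MU)
        total = sum(flows.values())
        scale = sum(abs(q) for q in flows.values())
        assert abs(total) / scale < 1e-10

    def test_floating_component_raises(self):
        g = VesselGraph(
            np.array([[0.0, 0.0], [1e-3, 0.0], [0.0, 1e-3], [1e-3, 1e-3]]),
            [(0, 1, 5e-6, 1e-3), (2, 3, 5e-6, 1e-3)],
            boundary_pressures={0: 100.0, 1: 0.0},
        )
        with pytest.raises(FlowConfigurationError):
            solve_vessel_pressure(g, MU)

    def test_wall_leak_lowers_dead_end_pressure(self):
        r, L = 5e-6, 1e-3
        g = VesselGraph(
            np.array([[0.0, 0.0], [L, 0.0], [2 * L, 0.0]]),
            [(0, 1, r, L), (1, 2, r, L)],
            boundary_pressures={0: 3000.0},
        )
        lam = np.full(2, 10.0 * edge_conductance(r, L, MU))
        p = solve_vessel_pressure(g, MU, leak_conductance=lam,
                                  leak_pressure=np.zeros(2))
        assert p[2] < p[1] < 3000.0


class TestStarlingExchange:
    def test_equilibrium_gives_zero_filtration(self):
        params = TissueParams()
        region = np.zeros((2, 2), bool)
        sig_dpi = params.normal.sigma_s * (params.normal.pi_b - params.normal.pi_i)
        P_b = np.full((2, 2), sig_dpi)
        phi_b, _ = starling_exchange(P_b, np.zeros((2, 2)), params, region,
                                     np.ones((2, 2)))
        assert np.allclose(phi_b, 0.0)

    def test_normal_tissue_hand_value(self):
        # L_p = 0.36e-7 cm/(mmHg s), S/V = 2e4 1/m, sigma_s = 0.91,
        # pi_b - pi_i = 10 mmHg, P_b = 3333 Pa, P_i = 0
        expected = (0.36e-7 * 1e-2 / 133.322) * 2.0e4 * (
            3333.0 - 0.91 * 10.0 * 133.322)
        assert expected == pytest.approx(1.14e-4, rel=0.005)
        params = TissueParams()
        region = np.zeros((1, 1), bool)
        phi_b, _ = starling_exchange(np.full((1, 1), 3333.0),
                                     np.zeros((1, 1)), params, region,
                                     np.ones((1, 1)))
        assert phi_b[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_tumor_has_no_lymphatic_drain(self):
        params = TissueParams()
        region = np.ones((3, 3), bool)
        _, phi_L = starling_exchange(np.full((3, 3), 3333.0),
                                     np.full((3, 3), 500.0), params, region,
                                     np.ones((3, 3)))
        assert np.all(phi_L == 0.0)

    def test_filtration_zero_away_from_vessels(self, small_flow):
        assert np.all(small_flow.phi_b[small_flow.vessel_weight == 0] == 0.0)

    def test_congruence_checked(self):
        params = TissueParams()
        with pytest.raises(ValueError):
            starling_exchange(np.zeros((2, 2)), np.zeros((3, 3)), params,
                              np.zeros((2, 2), bool), np.ones((2, 2)))


class TestSolveIFP:
    def test_no_source_gives_boundary_value(self):
        domain = DomainSpec().scaled(0.1)
        shape = (20, 22)
        region = domain.region_map_for_shape(shape)
        params = TissueParams(normal=normal_tissue_params(L_p=0.0, L_pL_SV=0.0),
                              tumor=tumor_tissue_params(L_p=0.0))
        P = solve_ifp(domain, params, region, np.ones(shape),
                      np.full(shape, 3000.0), boundary_pressure=0.0)
        assert np.allclose(P, 0.0, atol=1e-12)

    def test_bessel_oracle_equivalence(self):
        res = bessel_ifp_benchmark(n=200, alpha=6.0)
        assert res["l2_error"] < 0.02

    def test_bessel_error_decreases_with_refinement(self):
        e_coarse = bessel_ifp_benchmark(n=100)["l2_error"]
        e_fine = bessel_ifp_benchmark(n=200)["l2_error"]
        assert e_fine < e_coarse

    def test_maximum_principle(self, small_flow):
        min_offset = min(
            tumor_tissue_params().effective_filtration_pressure,
            normal_tissue_params().effective_filtration_pressure,
        )
        bound = small_flow.P_b_grid.max() - min_offset
        assert small_flow.P_i.max() <= bound + 1e-9


class TestDarcyVelocity:
    def test_uniform_pressure_zero_velocity(self):
        P = np.full((10, 12), 123.0)
        vx, vy = darcy_velocity(P, np.full_like(P, 1e-14), 1e-4, 1e-4)
        assert np.allclose(vx, 0.0) and np.allclose(vy, 0.0)

    def test_linear_ramp_exact(self):
        kappa, dx, dy = 2e-14, 1e-4, 1e-4
        ny, nx = 8, 14
        x = (np.arange(nx) + 0.5) * dx
        P = np.tile(1000.0 * x / (nx * dx), (ny, 1))
        grad = 1000.0 / (nx * dx)
        vx, vy = darcy_velocity(P, np.full((ny, nx), kappa), dx, dy)
        assert np.allclose(vx, -kappa * grad, rtol=1e-12)
        assert np.allclose(vy, 0.0, atol=1e-20)

    def test_paper_scale_velocity_magnitude(self, t2_flow):
        # printed maximum is ~1.78e-7 m/s; require the same order of magnitude
        *_, flow = t2_flow
        assert flow.speed.max() < 1e-6
        assert flow.speed.max() > 1e-8


class TestCoupleFlow:
    def test_zero_conductivity_decouples(self):
        cfg = small_case_config()
        domain, graph = build_vasculature(cfg)
        params = TissueParams(normal=normal_tissue_params(L_p=0.0),
                              tumor=tumor_tissue_params(L_p=0.0))
        flow = couple_flow(graph, domain, params, grid_shape=(45, 50),
                           raster_pixel_size=2e-5)
        assert np.allclose(flow.P_i, 0.0, atol=1e-10)
        p_ref = solve_vessel_pressure(graph)
        assert np.allclose(flow.node_pressures, p_ref)

    def test_residual_non_increasing_after_second_iteration(self, small_flow):
        res = small_flow.residual_history
        assert all(b <= a for a, b in zip(res[1:], res[2:]))

    def test_global_fluid_mass_balance(self, small_cfg, small_flow):
        bal = fluid_mass_balance(small_flow, small_cfg.build_params())
        assert bal.relative_imbalance < 0.01

    def test_max_iter_exceeded_raises_with_residuals(self):
        # quarter-scale dense fixture: the vessel/tissue coupling is strong
        # enough that two iterations cannot reach a tight tolerance
        cfg = small_case_config()
        cfg.domain.update(width_m=0.0672 / 4, height_m=0.0609 / 4,
                          tumor_diameter_m=0.023 / 4, grid_nx=60, grid_ny=54)
        domain, graph = build_vasculature(cfg)
        with pytest.raises(ConvergenceError) as exc:
            couple_flow(graph, domain, cfg.build_params(),
                        grid_shape=(54, 60), raster_pixel_size=2e-5,
                        tol=1e-12, max_iter=2)
        assert len(exc.value.residuals) >= 1

    def test_tumor_ifp_exceeds_normal_configuration(self):
        cfg = small_case_config()
        domain, graph = build_vasculature(cfg)
        kwargs = dict(grid_shape=(45, 50), raster_pixel_size=1e-5,
                      weight_smooth_m=2e-4)
        all_normal = TissueParams(normal=normal_tissue_params(),
                                  tumor=normal_tissue_params())
        flow_n = couple_flow(graph, domain, all_normal, **kwargs)
        flow_t = couple_flow(graph, domain, TissueParams(), **kwargs)
        tumor = flow_t.region_map
        assert flow_t.P_i[tumor].max() > flow_n.P_i[tumor].max()

    def test_tumor_lp_monotonicity(self):
        cfg = small_case_config()
        domain, graph = build_vasculature(cfg)
        kwargs = dict(grid_shape=(45, 50), raster_pixel_size=1e-5,
                      weight_smooth_m=2e-4)
        base = TissueParams()
        boosted = TissueParams(
            tumor=tumor_tissue_params(L_p=2 * base.tumor.L_p))
        f1 = couple_flow(graph, domain, base, **kwargs)
        f2 = couple_flow(graph, domain, boosted, **kwargs)
        tumor = f1.region_map
        assert f2.P_i[tumor].max() >= f1.P_i[tumor].max() - 1e-9

    def test_velocity_is_darcy_of_pressure(self, small_cfg, small_flow):
        # spot-check v = -kappa grad P on interior cells away from the rim
        ny, nx = small_flow.P_i.shape
        dx = small_flow.domain.width / nx
        kappa_n = small_cfg.build_params().normal.kappa
        i, j = 5, nx // 2  # well inside normal tissue, far from the tumor
        grad_x = (small_flow.P_i[i, j + 1] - small_flow.P_i[i, j - 1]) / (2 * dx)
        assert small_flow.v_x[i, j] == pytest.approx(-kappa_n * grad_x,
                                                     rel=0.05, abs=1e-12)


class TestVesselWeight:
    def test_region_means_are_unity(self, small_cfg, small_flow):
        w = small_flow.vessel_weight
        tumor = small_flow.region_map
        assert w[tumor].mean() == pytest.approx(1.0, rel=0.15)
        assert w[~tumor].mean() == pytest.approx(1.0, rel=0.15)

    def test_weight_nonnegative(self, small_flow):
        assert (small_flow.vessel_weight >= 0).all()
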