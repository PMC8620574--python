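import numpy as np
import pytest

from perfusim.aif import BiexponentialAIF, ConstantAIF, TabulatedAIF, ZeroAIF
from perfusim.transport import (SchemeError, TransportSolver,
                                lymphatic_solute_drain, peclet_factor,
                                peclet_number, run_simulation,
                                transvascular_solute_flux)
from perfusim.types import (ConcState, DomainSpec, FlowField, SimConfig,
                            TissueParams, normal_tissue_params)


def uniform_flow(n=8, phi_b=0.0, vx=0.0, vy=0.0, side=0.008):
    domain = DomainSpec(width=side, height=side, tumor_diameter=side / 4,
                        grid_spacing=side / n)
    shape = (n, n)
    return FlowField(
        domain=domain, node_pressures=np.empty(0),
        P_b_grid=np.zeros(shape), P_i=np.zeros(shape),
        v_x=np.full(shape, vx), v_y=np.full(shape, vy),
        phi_b=np.full(shape, phi_b), phi_L=np.zeros(shape),
        vessel_weight=np.ones(shape),
        region_map=domain.region_map_for_shape(shape), spacing=side / n,
    )


def uniform_params(**overrides) -> TissueParams:
    p = normal_tissue_params(**overrides)
    q = normal_tissue_params(**overrides)
    return TissueParams(normal=p, tumor=q)


class TestPecletNumber:
    def test_zero_filtration(self):
        assert np.all(peclet_number(np.zeros((2, 2)), 0.9, 3.75e-7, 2e4) == 0)

    def test_hand_value(self):
        expected = 1.14e-4 * (1 - 0.9) / (3.75e-7 * 2.0e4)
        assert expected == pytest.approx(1.52e-3, rel=1e-3)
        pe = peclet_number(np.full((1, 1), 1.14e-4), 0.9, 3.75e-7, 2.0e4)
        assert pe[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_doubling_permeability_halves_pe(self):
        pe1 = peclet_number(np.full((1, 1), 1e-4), 0.9, 3.75e-7, 2e4)
        pe2 = peclet_number(np.full((1, 1), 1e-4), 0.9, 7.5e-7, 2e4)
        assert pe1[0, 0] == pytest.approx(2 * pe2[0, 0])

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            peclet_number(np.full((1, 1), 1e-4), 0.9, 0.0, 2e4)


class TestPecletFactor:
    def test_unity_at_zero(self):
        assert peclet_factor(np.zeros(1))[0] == 1.0

    def test_series_matches_direct_near_crossover(self):
        pe = np.array([1e-7, 5e-7, 2e-6, 1e-5])
        direct = pe / np.expm1(pe)
        assert np.allclose(peclet_factor(pe), direct, rtol=1e-10)

    def test_large_pe_limits(self):
        assert peclet_factor(np.array([50.0]))[0] == pytest.approx(50.0 / np.expm1(50.0))
        assert peclet_factor(np.array([-50.0]))[0] == pytest.approx(50.0)


class TestTransvascularFlux:
    def test_pure_diffusion_limit(self):
        C_p, C_i = 80.0, 20.0
        psv = 7.5e-3
        flux = transvascular_solute_flux(C_p, np.full((1, 1), C_i),
                                         np.zeros((1, 1)), 0.9, psv)
        assert flux[0, 0] == pytest.approx(psv * (C_p - C_i))

    def test_equilibrated_no_flux(self):
        flux = transvascular_solute_flux(50.0, np.full((2, 2), 50.0),
                                         np.zeros((2, 2)), 0.9, 7.5e-3)
        assert np.allclose(flux, 0.0)

    def test_brute_force_formula_evaluation(self):
        # independent evaluation with mpmath-free exact arithmetic
        C_p, C_i, phi_b, sf, psv = 100.0, 0.0, 1.14e-4, 0.9, 7.5e-3
        pe = phi_b * (1 - sf) / psv
        expected = phi_b * (1 - sf) * C_p + psv * (C_p - C_i) * pe / (np.exp(pe) - 1)
        flux = transvascular_solute_flux(C_p, np.full((1, 1), C_i),
                                         np.full((1, 1), phi_b), sf, psv)
        assert flux[0, 0] == pytest.approx(expected, rel=1e-12)
        # sanity: close to 1.14e-3 + 0.75 minus an O(Pe/2) correction
        assert expected == pytest.approx(1.14e-3 + 0.75, rel=1e-3)


class TestLymphaticDrain:
    def test_zero_cases(self):
        assert np.all(lymphatic_solute_drain(np.zeros((2, 2)),
                                             np.full((2, 2), 1e-4)) == 0)
        assert np.all(lymphatic_solute_drain(np.full((2, 2), 10.0),
                                             np.zeros((2, 2))) == 0)

    def test_arithmetic(self):
        out = lymphatic_solute_drain(np.full((2, 2), 50.0),
                                     np.full((2, 2), 1e-4))
        assert np.allclose(out, 5e-3)


class TestAdvance:
    def test_frozen_state_unchanged(self):
        flow = uniform_flow(phi_b=0.0)
        params = uniform_params(D_eff=0.0, L3=0.0, L4=0.0, L5=0.0,
                                P_perm=0.0, L_pL_SV=0.0)
        solver = TransportSolver(flow.domain, flow, params, SimConfig(dt=1.0))
        c0 = np.random.default_rng(0).uniform(0, 10, (8, 8))
        state = ConcState(0.0, c0.copy(), np.zeros((8, 8)), np.zeros((8, 8)))
        new, _ = solver.advance(state, ZeroAIF())
        assert np.allclose(new.C_i, c0)
        assert np.all(new.C_e == 0) and np.all(new.C_m == 0)

    def test_kinetic_cascade_requires_l3(self):
        flow = uniform_flow()
        params = uniform_params(L3=0.0, P_perm=1e-9, L_pL_SV=0.0)
        solver = TransportSolver(flow.domain, flow, params, SimConfig(dt=1.0))
        state = ConcState(0.0, np.full((8, 8), 5.0), np.zeros((8, 8)),
                          np.zeros((8, 8)))
        for _ in range(20):
            state, _ = solver.advance(state, ZeroAIF())
        assert np.all(state.C_e == 0.0)
        assert np.all(state.C_m == 0.0)

    def test_cfl_violation_raises(self):
        flow = uniform_flow(vx=1.0)  # absurd velocity
        params = uniform_params()
        solver = TransportSolver(flow.domain, flow, params, SimConfig(dt=10.0))
        state = ConcState(0.0, np.zeros((8, 8)), np.zeros((8, 8)),
                          np.zeros((8, 8)))
        with pytest.raises(SchemeError):
            solver.advance(state, ZeroAIF())

    def test_closed_domain_conservation(self):
        # diffusion + uniform convection of a centered blob; no reactions
        n, side = 40, 0.008
        v = 1e-7
        flow = uniform_flow(n=n, side=side, vx=v, vy=v / 2)
        params = uniform_params(L3=0.0, L4=0.0, L5=0.0, P_perm=0.0,
                                L_pL_SV=0.0, D_eff=1e-10)
        flow.phi_b[:] = 0.0
        config = SimConfig(dt=100.0, conservative_advection=True)
        solver = TransportSolver(flow.domain, flow, params, config)
        c0 = np.zeros((n, n))
        c0[16:24, 16:24] = 1.0
        state = ConcState(0.0, c0, np.zeros((n, n)), np.zeros((n, n)))
        total0 = state.C_i.sum()
        for _ in range(50):
            state, _ = solver.advance(state, ZeroAIF())
        assert state.C_i.sum() == pytest.approx(total0, rel=1e-3)

    def test_uniform_configuration_matches_ode_oracle(self):
        from perfusim.pipeline import wellmixed_transport_benchmark

        res = wellmixed_transport_benchmark(t_end=3600.0, dt=1.0)
        assert res["rel_error"] < 1e-3
        assert res["uniform_spread"] < 1e-9


class TestRunSimulation:
    def test_zero_aif_keeps_everything_zero(self):
        flow = uniform_flow(phi_b=1e-4)
        params = uniform_params()
        config = SimConfig(dt=5.0, t_end=60.0, output_times=[30.0, 60.0])
        traj = run_simulation(flow.domain, flow, ZeroAIF(), params, config)
        for s in traj.states:
            assert np.all(s.C_total == 0.0)

    def test_tumor_mean_exceeds_normal_at_all_times(self, small_case):
        for s in small_case.trajectory.states:
            tumor = small_case.flow.region_map
            assert s.C_total[tumor].mean() > s.C_total[~tumor].mean()

    def test_cm_pointwise_nondecreasing(self, small_case):
        states = small_case.trajectory.states
        for a, b in zip(states[:-1], states[1:]):
            assert np.all(b.C_m >= a.C_m - 1e-14)

    def test_all_compartments_nonnegative(self, small_case):
        for s in small_case.trajectory.states:
            assert s.C_i.min() >= 0 and s.C_e.min() >= 0 and s.C_m.min() >= 0

    def test_free_tracer_dominates_early_at_tumor_center(self, small_case):
        tumor = small_case.flow.region_map
        for s in small_case.trajectory.states:
            if s.t <= 180.0:
                ny, nx = s.C_i.shape
                ci = s.C_i[ny // 2, nx // 2]
                ce = s.C_e[ny // 2, nx // 2]
                assert tumor[ny // 2, nx // 2]
                assert ci > ce

    def test_output_times_honored(self, small_case):
        assert small_case.trajectory.times == [60.0, 120.0, 180.0, 600.0,
                                               1800.0, 3600.0]


class TestAIF:
    def test_biexponential_starts_at_zero_and_nonnegative(self):
        aif = BiexponentialAIF()
        t = np.linspace(0, 7200, 500)
        assert aif(0.0) == 0.0
        assert np.all(aif(t) >= 0.0)

    def test_constant_and_tabulated(self, tmp_path):
        c = ConstantAIF(5.0)
        assert c(123.0) == 5.0
        tab = TabulatedAIF(np.array([0.0, 10.0, 20.0]),
                           np.array([0.0, 4.0, 2.0]))
        assert tab(5.0) == pytest.approx(2.0)
        path = tmp_path / "aif.csv"
        tab.to_csv(path)
        back = TabulatedAIF.from_csv(path)
        assert np.array_equal(back.times, tab.times)
        assert np.array_equal(back.values, tab.values)

    def test_validation(self):
        with pytest.raises(ValueError):
            BiexponentialAIF(k_rise=0.001, k_decay=0.01)
        with pytest.raises(ValueError):
            TabulatedAIF(np.array([0.0, 1.0]), np.array([0.0, -1.0]))
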