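"""High-level case runner tying the modules together."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CaseConfig
from .flow import couple_flow
from .synth import (assign_boundary_pressures, capillary_subgraph,
                    generate_network, rasterize)
from .transport import Trajectory, run_simulation
from .types import DomainSpec, FlowField, TissueParams, VesselGraph


@dataclass
class CaseResult:
    config: CaseConfig
    domain: DomainSpec
    graph: VesselGraph
    flow: FlowField
    trajectory: Trajectory | None


def build_vasculature(cfg: CaseConfig) -> tuple[DomainSpec, VesselGraph]:
    domain = cfg.build_domain()
    graph = generate_network(domain, cfg.build_network_spec())
    assign_boundary_pressures(graph, cfg.inlet_pressure_pa, cfg.outlet_pressure_pa)
    return domain, graph


def solve_flow(cfg: CaseConfig, domain: DomainSpec, graph: VesselGraph,
               grid_shape: tuple[int, int] | None = None,
               vessel_mask=None) -> FlowField:
    f = cfg.flow
    return couple_flow(
        graph, domain, cfg.build_params(),
        grid_shape=grid_shape or cfg.grid_shape(),
        viscosity=float(f["viscosity_pa_s"]),
        raster_pixel_size=float(cfg.vasculature["raster_pixel_m"]),
        vessel_mask=vessel_mask,
        boundary_pressure=float(f["outer_boundary_pressure_pa"]),
        weight_smooth_m=float(f.get("vessel_weight_smooth_m", 0.0)),
        interface_blend_m=float(f.get("interface_blend_m", 0.0)),
        tol=float(f["tol"]), max_iter=int(f["max_iter"]),
    )


def run_case(cfg: CaseConfig, with_transport: bool = True) -> CaseResult:
    domain, graph = build_vasculature(cfg)
    flow = solve_flow(cfg, domain, graph)
    trajectory = None
    if with_transport:
        trajectory = run_simulation(domain, flow, cfg.build_aif(),
                                    cfg.build_params(), cfg.build_sim_config())
    return CaseResult(cfg, domain, graph, flow, trajectory)


# ---------------------------------------------------------------------------
# oracle benchmarks (solver vs closed form)
# ---------------------------------------------------------------------------

def bessel_ifp_benchmark(n: int = 200, alpha: float = 6.0, R: float = 0.01,
                         P_e: float = 1000.0, kappa: float = 1e-14
                         ) -> dict[str, float]:
    """Uniform-source disc IFP vs the modified-Bessel analytic solution.

    A disc of radius R carries a uniform filtration coefficient
    b = kappa alpha^2 / R^2 toward effective pressure P_e; the exterior ring
    is given an overwhelming lymphatic sink, clamping P to ~0 at the rim so
    the grid solves the same boundary-value problem as the closed form.
    Returns the relative L2 error over the disc interior.
    """
    from .flow import solve_ifp
    from .oracles import radial_ifp_analytic
    from .types import RegionParams, TissueParams

    b = kappa * alpha**2 / R**2
    side = 2.4 * R
    domain = DomainSpec(width=side, height=side, tumor_diameter=2 * R,
                        grid_spacing=side / n)
    shape = (n, n)
    region = domain.region_map_for_shape(shape)
    weight = np.ones(shape)
    P_b = 2.0 * P_e  # with sigma_s*(pi_b - pi_i) = P_e the target is P_e
    common = dict(S_over_V=1.0, sigma_s=0.5, pi_b=2.0 * P_e, pi_i=0.0,
                  kappa=kappa, P_L=0.0, D_eff=0.0, P_perm=0.0, sigma_f=0.9,
                  L3=0.0, L4=0.0, L5=0.0)
    params = TissueParams(
        normal=RegionParams(L_p=0.0, L_pL_SV=1e4 * b, **common),
        tumor=RegionParams(L_p=b, L_pL_SV=0.0, **common),
    )
    P = solve_ifp(domain, params, region, weight,
                  np.full(shape, P_b), boundary_pressure=0.0)

    x = (np.arange(n) + 0.5) * side / n
    xx, yy = np.meshgrid(x, domain.height - x)
    rr = np.hypot(xx - domain.tumor_center[0], yy - domain.tumor_center[1])
    inside = rr <= R * (1.0 - 2.0 / n)  # keep clear of the rim staircase
    exact = radial_ifp_analytic(R, P_e, alpha, np.clip(rr[inside], 0, R))
    err = np.linalg.norm(P[inside] - exact) / np.linalg.norm(exact)
    return {"l2_error": float(err), "n": n, "alpha": alpha,
            "max_numeric": float(P[inside].max()), "plateau": P_e}


def wellmixed_transport_benchmark(t_end: float = 3600.0, dt: float = 1.0,
                                  n: int = 8) -> dict[str, float]:
    """Spatially uniform PDE trajectory vs the matrix-exponential oracle.

    Uniform fields and zero velocity reduce the transport solver to the
    well-mixed three-compartment ODE at every cell; the relative error of
    (C_i, C_e, C_m) at t_end against the closed-form solution is returned.
    """
    from .aif import BiexponentialAIF
    from .oracles import WellMixedParams, wellmixed_solution
    from .transport import TransportSolver
    from .types import (ConcState, SimConfig, TissueParams,
                        normal_tissue_params)

    params = TissueParams(normal=normal_tissue_params(),
                          tumor=normal_tissue_params())
    p = params.normal
    domain = DomainSpec(width=0.008, height=0.008, tumor_diameter=0.002,
                        grid_spacing=0.008 / n)
    shape = (n, n)
    region = domain.region_map_for_shape(shape)
    phi_b = 1.14e-4
    flow = FlowField(
        domain=domain, node_pressures=np.empty(0),
        P_b_grid=np.zeros(shape), P_i=np.zeros(shape),
        v_x=np.zeros(shape), v_y=np.zeros(shape),
        phi_b=np.full(shape, phi_b), phi_L=np.full(shape, p.L_pL_SV * 0.0),
        vessel_weight=np.ones(shape), region_map=region, spacing=0.008 / n,
    )
    aif = BiexponentialAIF()
    config = SimConfig(dt=dt, t_end=t_end, output_times=[t_end])
    solver = TransportSolver(domain, flow, params, config)
    state = ConcState(0.0, np.zeros(shape), np.zeros(shape), np.zeros(shape))
    while state.t < t_end - 1e-9:
        state, _ = solver.advance(state, aif, min(dt, t_end - state.t))

    wm = WellMixedParams(L3=p.L3, L4=p.L4, L5=p.L5, sigma_f=p.sigma_f,
                         PSV=p.P_perm * p.S_over_V, phi_b=phi_b, phi_L=0.0)
    ci, ce, cm = wellmixed_solution(wm, aif, [t_end])
    exact = np.array([ci[0], ce[0], cm[0]])
    numeric = np.array([state.C_i.mean(), state.C_e.mean(), state.C_m.mean()])
    uniform_spread = max(
        float(np.ptp(state.C_i)), float(np.ptp(state.C_e)),
        float(np.ptp(state.C_m)))
    err = float(np.max(np.abs(numeric - exact) / np.abs(exact)))
    return {"rel_error": err, "t_end": t_end, "dt": dt,
            "uniform_spread": uniform_spread}


# ---------------------------------------------------------------------------
# mesh convergence study
# ---------------------------------------------------------------------------

def case_metrics(domain: DomainSpec, flow: FlowField,
                 trajectory: Trajectory | None) -> dict[str, float]:
    tumor = flow.region_map
    metrics = {
        "max_tumor_ifp_pa": float(flow.P_i[tumor].max()),
        "max_ifv_m_per_s": float(flow.speed.max()),
    }
    if trajectory is not None and trajectory.states:
        final = trajectory.states[-1]
        metrics["tumor_median_c_total"] = float(np.median(final.C_total[tumor]))
    return metrics


def mesh_convergence(cfg: CaseConfig, refinement_factors=(1, 2, 4),
                     with_transport: bool = True) -> pd.DataFrame:
    """Re-solve one fixed case at successive grid refinements.

    The vasculature and its rasterization are generated once, so refinement
    changes only the tissue grid.  Reports each tracked metric per level and
    the relative change between consecutive levels; the finest-pair changes
    are the grid-independence figure of merit (target < 2.5%).
    """
    factors = list(refinement_factors)
    if any(b < a for a, b in zip(factors, factors[1:])):
        raise ValueError("refinement_factors must be non-decreasing")
    domain, graph = build_vasculature(cfg)
    mask = rasterize(capillary_subgraph(graph),
                     float(cfg.vasculature["raster_pixel_m"]),
                     width=domain.width, height=domain.height)
    ny0, nx0 = cfg.grid_shape()
    rows = []
    prev: dict[str, float] | None = None
    for factor in factors:
        shape = (int(ny0 * factor), int(nx0 * factor))
        flow = solve_flow(cfg, domain, graph, grid_shape=shape, vessel_mask=mask)
        trajectory = None
        if with_transport:
            trajectory = run_simulation(domain, flow, cfg.build_aif(),
                                        cfg.build_params(), cfg.build_sim_config())
        metrics = case_metrics(domain, flow, trajectory)
        row = {"factor": factor, "ny": shape[0], "nx": shape[1], **metrics}
        if prev is not None:
            for key, value in metrics.items():
                denom = max(abs(value), abs(prev[key]), 1e-300)
                row[f"rel_change_{key}"] = abs(value - prev[key]) / denom
        rows.append(row)
        prev = metrics
    df = pd.DataFrame(rows)
    change_cols = [c for c in df.columns if c.startswith("rel_change_")]
    df.attrs["finest_pair_max_change"] = float(
        df.iloc[-1][change_cols].max()) if change_cols else np.nan
    df.attrs["all_below_2_5pct"] = bool(
        (df.iloc[-1][change_cols] < 0.025).all()) if change_cols else False
    return df
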