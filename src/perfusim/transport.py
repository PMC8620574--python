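"""Three-compartment convection-diffusion-reaction tracer transport.

State variables on the tissue grid (mol/m^3):

* ``C_i`` extracellular free tracer — diffuses (region-dependent effective
  diffusivity), is advected by the steady interstitial velocity, exchanges
  with plasma (Patlak transvascular flux), drains into lymphatics, and
  exchanges with the cell interior at rates L3/L4;
* ``C_e`` intracellular free tracer — pure kinetics;
* ``C_m`` phosphorylated tracer — irreversibly produced from C_e at L5.

Time integration is operator-split: explicit (sub-stepped) linear kinetics
and exchange, explicit first-order upwind convection (CFL-checked), implicit
diffusion with a cached sparse factorization.  The outer boundary carries a
zero-normal-gradient (open) condition; the tumor interface is handled by the
flux-conservative discretization with harmonic diffusivity averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .aif import AIFCurve
from .types import ConcState, DomainSpec, FlowField, SimConfig, TissueParams


class SchemeError(RuntimeError):
    """Raised when the step size violates the scheme's stability contract."""


# ---------------------------------------------------------------------------
# pointwise terms
# ---------------------------------------------------------------------------

def peclet_number(phi_b, sigma_f, P_perm, S_over_V):
    """Transvascular Peclet number phi_b (1 - sigma_f) / (P S/V).

    Elementwise on grids; a zero denominator where filtration is active is a
    configuration error.
    """
    phi_b = np.asarray(phi_b, dtype=float)
    denom = np.asarray(P_perm, dtype=float) * np.asarray(S_over_V, dtype=float)
    denom = np.broadcast_to(denom, phi_b.shape)
    bad = (denom <= 0) & (phi_b != 0)
    if np.any(bad):
        raise ValueError("P_perm * S_over_V must be positive where phi_b != 0")
    out = np.zeros_like(phi_b)
    ok = denom > 0
    sf = np.broadcast_to(np.asarray(sigma_f, dtype=float), phi_b.shape)
    out[ok] = phi_b[ok] * (1.0 - sf[ok]) / denom[ok]
    return out


def peclet_factor(pe):
    """Numerically stable Pe / (exp(Pe) - 1); equals 1 at Pe = 0."""
    pe = np.asarray(pe, dtype=float)
    out = np.empty_like(pe)
    small = np.abs(pe) < 1e-6
    ps = pe[small]
    out[small] = 1.0 - ps / 2.0 + ps**2 / 12.0
    out[~small] = pe[~small] / np.expm1(pe[~small])
    return out


def transvascular_solute_flux(C_p, C_i, phi_b, sigma_f, PSV):
    """Patlak flux: phi_b (1-sigma_f) C_p + (P S/V)(C_p - C_i) Pe/(e^Pe - 1)."""
    phi_b = np.asarray(phi_b, dtype=float)
    pe = peclet_number(phi_b, sigma_f, P_perm=PSV, S_over_V=1.0)
    return (phi_b * (1.0 - np.asarray(sigma_f)) * C_p
            + np.asarray(PSV) * (C_p - np.asarray(C_i)) * peclet_factor(pe))


def lymphatic_solute_drain(C_i, phi_L):
    """Solute loss to lymphatics: phi_L * C_i."""
    return np.asarray(phi_L, dtype=float) * np.asarray(C_i, dtype=float)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

@dataclass
class StepDiagnostics:
    t: float
    mass_change: float        # integral of d(C_i+C_e+C_m) over the domain
    source_mass: float        # dt * integral(Phi_bt - Phi_Lt)
    advective_outflow: float  # mass advected across the outer boundary

    @property
    def relative_imbalance(self) -> float:
        scale = max(abs(self.mass_change), abs(self.source_mass), 1e-300)
        return abs(self.mass_change - (self.source_mass - self.advective_outflow)) / scale


class TransportSolver:
    """Stateful integrator bound to one steady flow field."""

    def __init__(self, domain: DomainSpec, flow: FlowField,
                 params: TissueParams, config: SimConfig | None = None):
        self.domain = domain
        self.flow = flow
        self.params = params
        self.config = config or SimConfig()
        self.region_map = flow.region_map
        ny, nx = self.region_map.shape
        self.shape = (ny, nx)
        self.dx = domain.width / nx
        self.dy = domain.height / ny
        self.cell_area = self.dx * self.dy

        # exchange fields localized on the vessels via the flow's weight grid
        w = flow.vessel_weight
        self.PSV = (params.grid("P_perm", self.region_map)
                    * params.grid("S_over_V", self.region_map) * w)
        self.sigma_f = params.grid("sigma_f", self.region_map)
        self.L3 = params.grid("L3", self.region_map)
        self.L4 = params.grid("L4", self.region_map)
        self.L5 = params.grid("L5", self.region_map)
        self.D = params.grid("D_eff", self.region_map)
        self.phi_b = flow.phi_b
        self.phi_L = flow.phi_L
        self.pe = peclet_number(self.phi_b, self.sigma_f, self.PSV, 1.0)
        self.pe_factor = peclet_factor(self.pe)

        self._diff_lu: dict[float, spla.SuperLU] = {}
        self._diff_op = self._build_diffusion_operator()

        # stability bound for the explicit kinetics/exchange update
        self._loss_rate_max = float(
            (self.L3 + self.PSV * self.pe_factor + self.phi_L).max()
        )

    # -- operators ---------------------------------------------------------

    def _build_diffusion_operator(self) -> sp.csr_matrix:
        """FV -div(D grad .) with zero-flux outer boundary."""
        ny, nx = self.shape
        n = ny * nx
        idx = np.arange(n).reshape(ny, nx)
        diag = np.zeros((ny, nx))
        rows, cols, vals = [], [], []

        def face(da, db):
            s = da + db
            return np.where(s > 0, 2.0 * da * db / np.where(s > 0, s, 1.0), 0.0)

        fx = face(self.D[:, :-1], self.D[:, 1:]) / self.dx**2
        diag[:, :-1] += fx
        diag[:, 1:] += fx
        rows.extend(idx[:, :-1].ravel()); cols.extend(idx[:, 1:].ravel()); vals.extend(-fx.ravel())
        rows.extend(idx[:, 1:].ravel()); cols.extend(idx[:, :-1].ravel()); vals.extend(-fx.ravel())
        fy = face(self.D[:-1, :], self.D[1:, :]) / self.dy**2
        diag[:-1, :] += fy
        diag[1:, :] += fy
        rows.extend(idx[:-1, :].ravel()); cols.extend(idx[1:, :].ravel()); vals.extend(-fy.ravel())
        rows.extend(idx[1:, :].ravel()); cols.extend(idx[:-1, :].ravel()); vals.extend(-fy.ravel())
        return sp.coo_matrix(
            (np.concatenate([np.asarray(vals), diag.ravel()]),
             (np.concatenate([np.asarray(rows), np.arange(n)]),
              np.concatenate([np.asarray(cols), np.arange(n)]))),
            shape=(n, n),
        ).tocsr()

    def _diffusion_solver(self, dt: float) -> spla.SuperLU:
        key = round(dt, 12)
        if key not in self._diff_lu:
            n = self.shape[0] * self.shape[1]
            A = sp.identity(n, format="csr") + dt * self._diff_op
            self._diff_lu[key] = spla.splu(A.tocsc())
        return self._diff_lu[key]

    # -- sub-steps ---------------------------------------------------------

    def _kinetics_step(self, state: ConcState, C_p: float, dt: float
                       ) -> tuple[ConcState, float]:
        """Explicit Euler on exchange + linear kinetics; sub-stepped for
        stability.  Returns (new state, source mass added to the domain)."""
        n_sub = max(1, int(np.ceil(dt * self._loss_rate_max / 0.2)))
        h = dt / n_sub
        C_i, C_e, C_m = state.C_i, state.C_e, state.C_m
        source_mass = 0.0
        for _ in range(n_sub):
            Phi_bt = (self.phi_b * (1.0 - self.sigma_f) * C_p
                      + self.PSV * (C_p - C_i) * self.pe_factor)
            Phi_Lt = self.phi_L * C_i
            dCi = -self.L3 * C_i + self.L4 * C_e + Phi_bt - Phi_Lt
            dCe = self.L3 * C_i - (self.L4 + self.L5) * C_e
            dCm = self.L5 * C_e
            C_i = C_i + h * dCi
            C_e = C_e + h * dCe
            C_m = C_m + h * dCm
            source_mass += h * float((Phi_bt - Phi_Lt).sum()) * self.cell_area
        return ConcState(state.t, C_i, C_e, C_m), source_mass

    def _advection_step(self, C: np.ndarray, dt: float) -> tuple[np.ndarray, float]:
        """First-order upwind convection of C_i.  Returns (new C, boundary
        outflow mass).  The outer boundary is zero-gradient (open)."""
        vx, vy = self.flow.v_x, self.flow.v_y
        cfl = float((np.abs(vx) / self.dx + np.abs(vy) / self.dy).max() * dt)
        if cfl > 1.0:
            raise SchemeError(f"advection CFL {cfl:.3f} > 1; reduce dt")
        if self.config.conservative_advection:
            return self._advection_conservative(C, dt)
        # non-conservative advective form v . grad C, upwind differences.
        # note: row index i increases downward => d/dy uses reversed rows
        dCdx_m = (C - np.roll(C, 1, axis=1)) / self.dx   # backward
        dCdx_p = (np.roll(C, -1, axis=1) - C) / self.dx  # forward
        dCdx_m[:, 0] = 0.0
        dCdx_p[:, -1] = 0.0
        dCdy_m = (C - np.roll(C, -1, axis=0)) / self.dy  # backward in y = down a row
        dCdy_p = (np.roll(C, 1, axis=0) - C) / self.dy
        dCdy_m[-1, :] = 0.0
        dCdy_p[0, :] = 0.0
        adv = (np.where(vx > 0, vx * dCdx_m, vx * dCdx_p)
               + np.where(vy > 0, vy * dCdy_m, vy * dCdy_p))
        C_new = C - dt * adv
        outflow = self._boundary_advective_outflow(C, dt)
        return C_new, outflow

    def _advection_conservative(self, C: np.ndarray, dt: float
                                ) -> tuple[np.ndarray, float]:
        """Finite-volume upwind flux form (conserves mass to round-off)."""
        vx, vy = self.flow.v_x, self.flow.v_y
        # interior x-faces between columns j and j+1
        vf = 0.5 * (vx[:, :-1] + vx[:, 1:])
        Fx = np.where(vf > 0, vf * C[:, :-1], vf * C[:, 1:])  # positive -> +x
        # interior y-faces between rows i (upper) and i+1 (lower); +y is up
        vfy = 0.5 * (vy[:-1, :] + vy[1:, :])
        Fy = np.where(vfy > 0, vfy * C[1:, :], vfy * C[:-1, :])  # positive -> up
        div = np.zeros_like(C)
        div[:, :-1] += Fx / self.dx
        div[:, 1:] -= Fx / self.dx
        div[1:, :] += Fy / self.dy    # flux up leaves the lower row...
        div[:-1, :] -= Fy / self.dy   # ...and enters the upper row
        # open outer boundary: upwind with zero-gradient exterior state
        out = 0.0
        left = np.where(vx[:, 0] < 0, vx[:, 0] * C[:, 0], 0.0)
        div[:, 0] += -left / self.dx
        out += float(-left.sum()) * self.dy
        right = np.where(vx[:, -1] > 0, vx[:, -1] * C[:, -1], 0.0)
        div[:, -1] += right / self.dx
        out += float(right.sum()) * self.dy
        top = np.where(vy[0, :] > 0, vy[0, :] * C[0, :], 0.0)
        div[0, :] += top / self.dy
        out += float(top.sum()) * self.dx
        bottom = np.where(vy[-1, :] < 0, vy[-1, :] * C[-1, :], 0.0)
        div[-1, :] += -bottom / self.dy
        out += float(-bottom.sum()) * self.dx
        return C - dt * div, out * dt

    def _boundary_advective_outflow(self, C: np.ndarray, dt: float) -> float:
        vx, vy = self.flow.v_x, self.flow.v_y
        out = 0.0
        out += float(np.where(vx[:, 0] < 0, -vx[:, 0] * C[:, 0], 0.0).sum()) * self.dy
        out += float(np.where(vx[:, -1] > 0, vx[:, -1] * C[:, -1], 0.0).sum()) * self.dy
        out += float(np.where(vy[0, :] > 0, vy[0, :] * C[0, :], 0.0).sum()) * self.dx
        out += float(np.where(vy[-1, :] < 0, -vy[-1, :] * C[-1, :], 0.0).sum()) * self.dx
        return out * dt

    # -- full step ---------------------------------------------------------

    def advance(self, state: ConcState, aif: AIFCurve, dt: float | None = None
                ) -> tuple[ConcState, StepDiagnostics]:
        """One operator-split step: kinetics/exchange, convection, diffusion."""
        dt = self.config.dt if dt is None else dt
        C_p = float(aif(state.t))
        mass0 = float(state.C_total.sum()) * self.cell_area

        state1, source_mass = self._kinetics_step(state, C_p, dt)
        C_i, outflow = self._advection_step(state1.C_i, dt)
        lu = self._diffusion_solver(dt)
        C_i = lu.solve(C_i.ravel()).reshape(self.shape)

        new = ConcState(state.t + dt, C_i, state1.C_e, state1.C_m)
        floor = -self.config.max_negative_tol * max(1.0, float(np.abs(C_i).max()))
        worst = min(new.C_i.min(), new.C_e.min(), new.C_m.min())
        if worst < floor:
            raise SchemeError(
                f"negative concentration {worst:.3e} beyond tolerance; dt too large"
            )
        np.clip(new.C_i, 0.0, None, out=new.C_i)
        np.clip(new.C_e, 0.0, None, out=new.C_e)
        np.clip(new.C_m, 0.0, None, out=new.C_m)
        mass1 = float(new.C_total.sum()) * self.cell_area
        diag = StepDiagnostics(new.t, mass1 - mass0, source_mass, outflow)
        return new, diag


def advance(state: ConcState, flow: FlowField, aif: AIFCurve,
            params: TissueParams, dt: float,
            config: SimConfig | None = None) -> ConcState:
    """Single-step convenience wrapper (rebuilds operators each call)."""
    solver = TransportSolver(flow.domain, flow, params, config)
    new, _ = solver.advance(state, aif, dt)
    return new


@dataclass
class Trajectory:
    states: list[ConcState]
    diagnostics: list[StepDiagnostics] = field(default_factory=list)

    @property
    def times(self) -> list[float]:
        return [s.t for s in self.states]

    def at(self, t: float) -> ConcState:
        for s in self.states:
            if abs(s.t - t) < 1e-6:
                return s
        raise KeyError(f"no state stored at t={t}")


def run_simulation(domain: DomainSpec, flow: FlowField, aif: AIFCurve,
                   params: TissueParams, config: SimConfig | None = None
                   ) -> Trajectory:
    """Integrate from zero initial concentrations, emitting ``output_times``."""
    config = config or SimConfig()
    solver = TransportSolver(domain, flow, params, config)
    ny, nx = solver.shape
    state = ConcState(0.0, np.zeros((ny, nx)), np.zeros((ny, nx)), np.zeros((ny, nx)))
    outputs = sorted(set(config.output_times))
    states: list[ConcState] = []
    diagnostics: list[StepDiagnostics] = []
    if outputs and abs(outputs[0]) < 1e-12:
        states.append(state.copy())
        outputs = outputs[1:]
    t_stops = list(outputs)
    if not t_stops or t_stops[-1] < config.t_end - 1e-9:
        t_stops.append(config.t_end)
    for t_target in t_stops:
        while state.t < t_target - 1e-9:
            dt = min(config.dt, t_target - state.t)
            state, diag = solver.advance(state, aif, dt)
            diagnostics.append(diag)
        if any(abs(state.t - t) < 1e-6 for t in outputs):
            states.append(state.copy())
    return Trajectory(states, diagnostics)
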