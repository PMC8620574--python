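"""Closed-form reference solutions used as independent test oracles.

These deliberately avoid the discretizations in :mod:`perfusim.flow` and
:mod:`perfusim.transport`: the well-mixed compartment system is solved by
matrix exponentials (exact for exponential-sum input functions, high-order
quadrature otherwise), and the axisymmetric interstitial-pressure problem by
its modified-Bessel solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.special import i0e, i1e

from .aif import AIFCurve
from .transport import peclet_factor


@dataclass
class WellMixedParams:
    """Scalar parameters of one homogeneous tissue point."""

    L3: float
    L4: float
    L5: float
    sigma_f: float
    PSV: float       # P_perm * S/V (possibly vessel-weighted), 1/s
    phi_b: float     # filtration rate, 1/s
    phi_L: float     # lymphatic drain rate, 1/s

    def __post_init__(self) -> None:
        for name in ("L3", "L4", "L5", "PSV", "phi_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def peclet(self) -> float:
        if self.phi_b == 0:
            return 0.0
        if self.PSV <= 0:
            raise ValueError("PSV must be positive when phi_b != 0")
        return self.phi_b * (1.0 - self.sigma_f) / self.PSV

    def system_matrix(self) -> np.ndarray:
        """A of x' = A x + u C_p(t), x = (C_i, C_e, C_m)."""
        eta = float(peclet_factor(self.peclet))
        return np.array([
            [-(self.L3 + self.PSV * eta + self.phi_L), self.L4, 0.0],
            [self.L3, -(self.L4 + self.L5), 0.0],
            [0.0, self.L5, 0.0],
        ])

    def forcing_vector(self) -> np.ndarray:
        eta = float(peclet_factor(self.peclet))
        s = self.phi_b * (1.0 - self.sigma_f) + self.PSV * eta
        return np.array([s, 0.0, 0.0])


def wellmixed_solution(params: WellMixedParams, aif: AIFCurve,
                       times) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact trajectory of the spatially uniform three-compartment system.

    For input functions that are finite sums of exponentials the solution is
    computed by augmented-matrix exponentials (exact to machine precision,
    including the singular C_m row).  Tabulated inputs fall back to a
    very-tight-tolerance stiff integration.
    """
    times = np.asarray(times, dtype=float)
    A = params.system_matrix()
    u = params.forcing_vector()

    if aif.exponential_terms is not None:
        # x(t) = sum_j c_j * (first 3 comps of expm(M_j t) e4),
        # M_j = [[A, u], [0, -lambda_j]]
        out = np.zeros((len(times), 3))
        for coef, lam in aif.exponential_terms:
            M = np.zeros((4, 4))
            M[:3, :3] = A
            M[:3, 3] = u
            M[3, 3] = -lam
            e4 = np.array([0.0, 0.0, 0.0, 1.0])
            for k, t in enumerate(times):
                out[k] += coef * (expm(M * t) @ e4)[:3]
        return out[:, 0], out[:, 1], out[:, 2]

    def rhs(t, x):
        return A @ x + u * float(aif(t))

    t_end = float(times.max()) if len(times) else 0.0
    sol = solve_ivp(rhs, (0.0, max(t_end, 1e-12)), np.zeros(3), method="LSODA",
                    t_eval=times, rtol=1e-11, atol=1e-12, max_step=np.inf)
    if not sol.success:
        raise RuntimeError(f"oracle integration failed: {sol.message}")
    return sol.y[0], sol.y[1], sol.y[2]


def wellmixed_stiff_reference(params: WellMixedParams, aif: AIFCurve,
                              times) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Independent cross-check: Radau integration of the same ODE system."""
    times = np.asarray(times, dtype=float)
    A = params.system_matrix()
    u = params.forcing_vector()

    def rhs(t, x):
        return A @ x + u * float(aif(t))

    sol = solve_ivp(rhs, (0.0, float(times.max())), np.zeros(3), method="Radau",
                    t_eval=times, rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    return sol.y[0], sol.y[1], sol.y[2]


def radial_ifp_analytic(R: float, P_e: float, alpha: float, r) -> np.ndarray:
    """Axisymmetric interstitial pressure in a uniformly perfused disc.

    Solves ``-kappa lap(P) + L_p (S/V) (P - P_e) = 0`` on r < R with
    P(R) = 0, where ``alpha = R sqrt(L_p (S/V) / kappa)``:

        P(r) = P_e (1 - I0(alpha r / R) / I0(alpha))

    evaluated with exponentially scaled Bessel functions for stability at
    large alpha.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > R * (1 + 1e-12))):
        raise ValueError("r must lie in [0, R]")
    if alpha == 0:
        return np.zeros_like(r)
    x = alpha * r / R
    ratio = i0e(x) / i0e(alpha) * np.exp(x - alpha)
    return P_e * (1.0 - ratio)


def radial_ifp_slope(R: float, P_e: float, alpha: float, r) -> np.ndarray:
    """dP/dr of the analytic disc solution (for velocity oracles)."""
    if alpha <= 0:
        return np.zeros_like(np.asarray(r, dtype=float))
    r = np.asarray(r, dtype=float)
    x = alpha * r / R
    ratio = i1e(x) / i0e(alpha) * np.exp(x - alpha)
    return -P_e * alpha / R * ratio
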