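"""Core domain types shared across the package.

Conventions
-----------
* All physical quantities are SI: pressures in Pa, lengths in m, times in s,
  concentrations in mol/m^3.
* Images are stored row-major with row 0 at the top.  Physical y increases
  upward, so pixel (i, j) has its center at
  ``x = (j + 0.5) * pixel_size``, ``y = (H - i - 0.5) * pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import units


# ---------------------------------------------------------------------------
# raster types
# ---------------------------------------------------------------------------

@dataclass
class RasterImage:
    """An RGB raster with a physical pixel size (m/px)."""

    pixels: np.ndarray  # (H, W, 3), uint8-compatible values in [0, 255]
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RasterImage requires an (H, W, 3) RGB array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be nonempty")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """Boolean foreground mask with a physical pixel size (m/px)."""

    values: np.ndarray  # (H, W) bool
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of every pixel center."""
        h, w = self.values.shape
        x = (np.arange(w) + 0.5) * self.pixel_size
        y = (h - np.arange(h) - 0.5) * self.pixel_size
        return x, y

    def area(self) -> float:
        """Foreground area in m^2."""
        return float(self.values.sum()) * self.pixel_size**2


# ---------------------------------------------------------------------------
# vessel graph
# ---------------------------------------------------------------------------

@dataclass
class VesselGraph:
    """Reduced centerline representation of a capillary network.

    nodes
        (N, 2) array of planar coordinates in meters.
    edges
        list of ``(u, v, radius_m, length_m)`` tuples referencing node rows.
    boundary_pressures
        mapping node index -> prescribed blood pressure (Pa).  Every
        connected component used for a flow solve must contain at least
        one entry.
    """

    nodes: np.ndarray
    edges: list[tuple[int, int, float, float]] = field(default_factory=list)
    boundary_pressures: dict[int, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 2)
        for (u, v, r, ell) in self.edges:
            if r <= 0 or ell <= 0:
                raise ValueError("edge radius and length must be positive")
            d = float(np.hypot(*(self.nodes[u] - self.nodes[v])))
            if ell < d - 1e-9:
                raise ValueError("edge length may not undercut node distance")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_length(self) -> float:
        return float(sum(e[3] for e in self.edges))

    def is_empty(self) -> bool:
        return self.n_edges == 0


# ---------------------------------------------------------------------------
# domain geometry and parameters
# ---------------------------------------------------------------------------

@dataclass
class DomainSpec:
    """Rectangular tissue slab with a centered circular tumor."""

    width: float = 0.0672
    height: float = 0.0609
    tumor_center: tuple[float, float] | None = None
    tumor_diameter: float = 0.023
    grid_spacing: float = 2.24e-4

    def __post_init__(self) -> None:
        if self.tumor_center is None:
            self.tumor_center = (self.width / 2.0, self.height / 2.0)
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        cx, cy = self.tumor_center
        r = self.tumor_diameter / 2.0
        if not (r < cx < self.width - r and r < cy < self.height - r):
            raise ValueError("tumor disc must lie strictly inside the domain")

    @property
    def tumor_radius(self) -> float:
        return self.tumor_diameter / 2.0

    def scaled(self, factor: float) -> "DomainSpec":
        """Geometrically similar domain shrunk/grown by ``factor``."""
        return DomainSpec(
            width=self.width * factor,
            height=self.height * factor,
            tumor_center=(self.tumor_center[0] * factor, self.tumor_center[1] * factor),
            tumor_diameter=self.tumor_diameter * factor,
            grid_spacing=self.grid_spacing * factor,
        )

    def grid_shape(self, spacing: float | None = None) -> tuple[int, int]:
        h = spacing if spacing is not None else self.grid_spacing
        return (max(1, round(self.height / h)), max(1, round(self.width / h)))

    def cell_centers(self, spacing: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (ascending) and y (descending, row order) centers."""
        ny, nx = self.grid_shape(spacing)
        dx = self.width / nx
        dy = self.height / ny
        x = (np.arange(nx) + 0.5) * dx
        y = self.height - (np.arange(ny) + 0.5) * dy
        return x, y

    def region_map(self, spacing: float | None = None) -> np.ndarray:
        """Boolean grid, True inside the tumor disc."""
        return self.region_map_for_shape(self.grid_shape(spacing))

    def region_map_for_shape(self, shape: tuple[int, int]) -> np.ndarray:
        """Tumor indicator on an arbitrary (ny, nx) cell-centered grid."""
        ny, nx = shape
        x = (np.arange(nx) + 0.5) * (self.width / nx)
        y = self.height - (np.arange(ny) + 0.5) * (self.height / ny)
        xx, yy = np.meshgrid(x, y)
        cx, cy = self.tumor_center
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.tumor_radius**2


@dataclass
class RegionParams:
    """Per-region physical parameters (SI units)."""

    L_p: float            # vascular hydraulic conductivity, m/(Pa s)
    S_over_V: float       # vessel surface area per tissue volume, 1/m
    sigma_s: float        # osmotic reflection coefficient
    pi_b: float           # blood osmotic pressure, Pa
    pi_i: float           # interstitial osmotic pressure, Pa
    kappa: float          # interstitial hydraulic conductivity, m^2/(Pa s)
    L_pL_SV: float        # lymphatic filtration coefficient, 1/(Pa s)
    P_L: float            # lymphatic pressure, Pa
    D_eff: float          # tracer effective diffusivity, m^2/s
    P_perm: float         # vascular solute permeability, m/s
    sigma_f: float        # filtration reflection coefficient
    L3: float             # cell internalization rate, 1/s
    L4: float             # cell efflux rate, 1/s
    L5: float             # phosphorylation rate, 1/s

    def __post_init__(self) -> None:
        for name in ("L_p", "S_over_V", "kappa", "L_pL_SV", "D_eff",
                     "P_perm", "L3", "L4", "L5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.sigma_s <= 1.0 and 0.0 <= self.sigma_f <= 1.0):
            raise ValueError("reflection coefficients must lie in [0, 1]")

    @property
    def effective_filtration_pressure(self) -> float:
        """Plateau pressure P_b_ref - sigma_s*(pi_b - pi_i) requires P_b;
        returned here as the osmotic offset only."""
        return self.sigma_s * (self.pi_b - self.pi_i)


def normal_tissue_params(**overrides) -> RegionParams:
    """Literature defaults for normal tissue."""
    base = dict(
        L_p=units.cm_per_mmhg_s(0.36e-7),
        S_over_V=2.0e4,
        sigma_s=0.91,
        pi_b=units.mmhg(20.0),
        pi_i=units.mmhg(10.0),
        kappa=6.41e-15,
        L_pL_SV=units.per_mmhg(1.33e-5),
        P_L=0.0,
        D_eff=3.7e-10,
        P_perm=3.75e-7,
        sigma_f=0.9,
        L3=units.per_min(8.2e-4),
        L4=units.per_min(6.7e-4),
        L5=units.per_min(5.3e-4),
    )
    base.update(overrides)
    return RegionParams(**base)


def tumor_tissue_params(**overrides) -> RegionParams:
    """Literature defaults for tumor tissue.

    Cell-exchange rates L3/L4 are not tabulated for tumor tissue; the
    fixture default multiplies the normal-tissue values by 10 (a stated
    convention, config-exposed).
    """
    base = dict(
        L_p=units.cm_per_mmhg_s(2.8e-7),
        S_over_V=2.0e4,
        sigma_s=0.82,
        pi_b=units.mmhg(20.0),
        pi_i=units.mmhg(15.0),
        kappa=30.0e-15,
        L_pL_SV=0.0,
        P_L=0.0,
        D_eff=2.5e-9,
        P_perm=3.00e-6,
        sigma_f=0.9,
        L3=units.per_min(8.2e-3),
        L4=units.per_min(6.7e-3),
        L5=units.per_min(5.3e-4),
    )
    base.update(overrides)
    return RegionParams(**base)


@dataclass
class TissueParams:
    """Normal + tumor parameter pair, with grid-expansion helpers."""

    normal: RegionParams = field(default_factory=normal_tissue_params)
    tumor: RegionParams = field(default_factory=tumor_tissue_params)

    def grid(self, attr: str, region_map: np.ndarray) -> np.ndarray:
        """Expand a scalar parameter onto a grid following region_map."""
        out = np.full(region_map.shape, getattr(self.normal, attr), dtype=float)
        out[region_map] = getattr(self.tumor, attr)
        return out


# ---------------------------------------------------------------------------
# flow and transport state
# ---------------------------------------------------------------------------

@dataclass
class FlowField:
    """Steady-state flow solution on a structured grid."""

    domain: DomainSpec
    node_pressures: np.ndarray          # P_b at graph nodes, Pa
    P_b_grid: np.ndarray                # blood pressure mapped to the grid, Pa
    P_i: np.ndarray                     # interstitial fluid pressure, Pa
    v_x: np.ndarray                     # IFV x-component, m/s
    v_y: np.ndarray                     # IFV y-component, m/s
    phi_b: np.ndarray                   # filtration rate, 1/s
    phi_L: np.ndarray                   # lymphatic drain rate, 1/s
    vessel_weight: np.ndarray           # local S/V scaling, region-mean 1
    region_map: np.ndarray              # True in tumor
    spacing: float
    n_iterations: int = 0
    residual_history: list[float] = field(default_factory=list)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.v_x, self.v_y)


@dataclass
class ConcState:
    """Tracer compartment concentrations at one time point (mol/m^3)."""

    t: float
    C_i: np.ndarray   # extracellular free tracer
    C_e: np.ndarray   # intracellular free tracer
    C_m: np.ndarray   # phosphorylated (trapped) tracer

    @property
    def C_total(self) -> np.ndarray:
        return self.C_i + self.C_e + self.C_m

    def copy(self) -> "ConcState":
        return ConcState(self.t, self.C_i.copy(), self.C_e.copy(), self.C_m.copy())


@dataclass
class SimConfig:
    """Time-integration controls."""

    dt: float = 1.0
    t_end: float = 3600.0
    output_times: Sequence[float] = (60.0, 120.0, 180.0, 600.0, 1800.0, 3600.0)
    conservative_advection: bool = False
    max_negative_tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for t in self.output_times:
            if not (0.0 <= t <= self.t_end + 1e-9):
                raise ValueError("output_times must lie in [0, t_end]")


@dataclass
class ProbeSpec:
    """Point probes and cutlines for time-activity reporting."""

    points: list[tuple[str, float, float]] = field(default_factory=list)
    cutlines: list[tuple[str, tuple[float, float], tuple[float, float], int]] = field(
        default_factory=list
    )


__all__ = [
    "RasterImage", "BinaryMask", "VesselGraph", "DomainSpec",
    "RegionParams", "TissueParams", "FlowField", "ConcState",
    "SimConfig", "ProbeSpec",
    "normal_tissue_params", "tumor_tissue_params", "replace",
]
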