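"""Case configuration: one YAML document describing a full simulation.

Every numeric field records its unit in the schema below; pressures given in
mmHg are converted to Pa when the objects are built.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import units
from .aif import AIFCurve, BiexponentialAIF, TabulatedAIF
from .synth import NetworkSpec
from .types import (DomainSpec, SimConfig, TissueParams,
                    normal_tissue_params, tumor_tissue_params)

SCHEMA_VERSION = 1


@dataclass
class CaseConfig:
    schema_version: int = SCHEMA_VERSION
    # [domain] meters
    domain: dict = field(default_factory=lambda: {
        "width_m": 0.0672,
        "height_m": 0.0609,
        "tumor_diameter_m": 0.023,
        "grid_nx": 300,
        "grid_ny": 270,
    })
    # [vasculature]
    vasculature: dict = field(default_factory=lambda: {
        "mvd_tumor_per_m": 8000.0,
        "mvd_normal_per_m": 2500.0,
        "n_parent_vessels": 4,
        "parent_radius_m": 40e-6,
        "capillary_radius_m": 5e-6,
        "seed": 0,
        "raster_pixel_m": 2.0e-5,
    })
    # [flow]
    flow: dict = field(default_factory=lambda: {
        "viscosity_pa_s": 3e-3,
        "inlet_pressure_mmhg": 25.0,
        "outlet_pressure_mmhg": 10.0,
        "outer_boundary_pressure_pa": 0.0,
        "vessel_weight_smooth_m": 1.0e-4,
        "interface_blend_m": 3.0e-4,
        "tol": 1e-8,
        "max_iter": 200,
    })
    # [tissue] optional SI overrides of the per-region defaults
    tissue: dict = field(default_factory=lambda: {"normal": {}, "tumor": {}})
    # [aif]
    aif: dict = field(default_factory=lambda: {
        "type": "biexponential",
        "amplitude_mol_per_m3": 1200.0,
        "k_rise_per_s": 1.0 / 30.0,
        "k_decay_per_s": 1.0 / 8000.0,
    })
    # [transport]
    transport: dict = field(default_factory=lambda: {
        "dt_s": 1.0,
        "t_end_s": 3600.0,
        "output_times_s": [60.0, 120.0, 180.0, 600.0, 1800.0, 3600.0],
        "conservative_advection": False,
    })
    seed: int = 0

    # -- builders ----------------------------------------------------------

    def build_domain(self) -> DomainSpec:
        d = self.domain
        nx = int(d["grid_nx"])
        return DomainSpec(
            width=float(d["width_m"]), height=float(d["height_m"]),
            tumor_diameter=float(d["tumor_diameter_m"]),
            grid_spacing=float(d["width_m"]) / nx,
        )

    def grid_shape(self) -> tuple[int, int]:
        return (int(self.domain["grid_ny"]), int(self.domain["grid_nx"]))

    def build_network_spec(self) -> NetworkSpec:
        v = self.vasculature
        return NetworkSpec(
            mvd_tumor=float(v["mvd_tumor_per_m"]),
            mvd_normal=float(v["mvd_normal_per_m"]),
            n_parent_vessels=int(v["n_parent_vessels"]),
            parent_radius=float(v["parent_radius_m"]),
            capillary_radius=float(v["capillary_radius_m"]),
            seed=int(v.get("seed", self.seed)),
        )

    def build_params(self) -> TissueParams:
        return TissueParams(
            normal=normal_tissue_params(**self.tissue.get("normal", {})),
            tumor=tumor_tissue_params(**self.tissue.get("tumor", {})),
        )

    def build_aif(self) -> AIFCurve:
        a = self.aif
        if a["type"] == "biexponential":
            return BiexponentialAIF(
                amplitude=float(a["amplitude_mol_per_m3"]),
                k_rise=float(a["k_rise_per_s"]),
                k_decay=float(a["k_decay_per_s"]),
            )
        if a["type"] == "csv":
            return TabulatedAIF.from_csv(a["path"])
        raise ValueError(f"unknown AIF type {a['type']!r}")

    def build_sim_config(self) -> SimConfig:
        t = self.transport
        return SimConfig(
            dt=float(t["dt_s"]), t_end=float(t["t_end_s"]),
            output_times=[float(x) for x in t["output_times_s"]],
            conservative_advection=bool(t.get("conservative_advection", False)),
            seed=self.seed,
        )

    @property
    def inlet_pressure_pa(self) -> float:
        return units.mmhg(float(self.flow["inlet_pressure_mmhg"]))

    @property
    def outlet_pressure_pa(self) -> float:
        return units.mmhg(float(self.flow["outlet_pressure_mmhg"]))

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CaseConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                merged = dict(getattr(cfg, key))
                merged.update(value)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg
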