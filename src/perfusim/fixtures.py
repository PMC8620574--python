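"""Canonical benchmark fixtures (seeded synthetic-vasculature cases).

These two configurations are the reference cases used by the validation
suite and the acceptance report:

* :func:`ifp_benchmark_config` — full-size domain with a dense tumor
  network and a uniform 25 mmHg capillary pressure; the maximum tumor IFP
  of its coupled flow solution is compared against the ~2.74 kPa benchmark
  (analytically capped by P_b - sigma_s*(pi_b - pi_i) = 2.79 kPa).
* :func:`convergence_benchmark_config` — geometrically similar 1/8-scale
  domain used for the three-level grid-independence study (target: < 2.5%
  change between the two finest levels).
"""

from __future__ import annotations

from .config import CaseConfig


def ifp_benchmark_config(seed: int = 0) -> CaseConfig:
    cfg = CaseConfig()
    cfg.seed = seed
    cfg.vasculature.update(
        mvd_tumor_per_m=6000.0,
        mvd_normal_per_m=2500.0,
        capillary_radius_m=1.0e-5,
        seed=seed,
    )
    cfg.flow.update(inlet_pressure_mmhg=25.0, outlet_pressure_mmhg=25.0)
    return cfg


def convergence_benchmark_config(seed: int = 0) -> CaseConfig:
    cfg = CaseConfig()
    scale = 8.0
    cfg.seed = seed
    cfg.domain.update(
        width_m=0.0672 / scale,
        height_m=0.0609 / scale,
        tumor_diameter_m=0.023 / scale,
        grid_nx=70,
        grid_ny=63,
    )
    cfg.vasculature.update(raster_pixel_m=1.0e-5, capillary_radius_m=8.0e-6,
                           seed=seed)
    cfg.flow.update(
        inlet_pressure_mmhg=25.0,
        outlet_pressure_mmhg=25.0,
        vessel_weight_smooth_m=4.0e-4,
        interface_blend_m=5.0e-4,
    )
    cfg.transport.update(dt_s=2.0)
    return cfg
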