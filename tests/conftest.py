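import warnings

import numpy as np
import pytest

from perfusim.config import CaseConfig
from perfusim.pipeline import build_vasculature, run_case, solve_flow

warnings.filterwarnings(
    "ignore", message="pixel_size exceeds the smallest vessel radius"
)


def small_case_config(seed: int = 0, **overrides) -> CaseConfig:
    """Desk-scale fixture: 1/8-size domain on a 50x45 grid."""
    cfg = CaseConfig()
    scale = 8.0
    cfg.seed = seed
    cfg.domain.update(
        width_m=0.0672 / scale, height_m=0.0609 / scale,
        tumor_diameter_m=0.023 / scale, grid_nx=50, grid_ny=45,
    )
    cfg.vasculature.update(raster_pixel_m=1e-5, capillary_radius_m=8e-6,
                           seed=seed)
    cfg.flow.update(inlet_pressure_mmhg=25.0, outlet_pressure_mmhg=25.0,
                    vessel_weight_smooth_m=2e-4)
    cfg.transport.update(dt_s=2.0)
    for key, value in overrides.items():
        if isinstance(getattr(cfg, key, None), dict):
            getattr(cfg, key).update(value)
        else:
            setattr(cfg, key, value)
    return cfg




@pytest.fixture(scope="session")
def small_cfg():
    return small_case_config()


@pytest.fixture(scope="session")
def small_vasculature(small_cfg):
    return build_vasculature(small_cfg)


@pytest.fixture(scope="session")
def small_flow(small_cfg, small_vasculature):
    domain, graph = small_vasculature
    return solve_flow(small_cfg, domain, graph)


@pytest.fixture(scope="session")
def small_case():
    """Full small simulation (flow + transport at the default AIF)."""
    return run_case(small_case_config(), with_transport=True)


@pytest.fixture(scope="session")
def t2_flow():
    """Full-scale coupled flow solution used by the IFP/IFV acceptance tests."""
    from perfusim.fixtures import ifp_benchmark_config

    cfg = ifp_benchmark_config()
    domain, graph = build_vasculature(cfg)
    return cfg, domain, graph, solve_flow(cfg, domain, graph)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
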