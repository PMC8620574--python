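"""Array and visualization output (NPZ, ASCII VTK, summary CSV)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .transport import Trajectory
from .types import FlowField


def save_flow_npz(flow: FlowField, path: str | Path) -> None:
    np.savez(
        Path(path), P_i=flow.P_i, P_b_grid=flow.P_b_grid, v_x=flow.v_x,
        v_y=flow.v_y, phi_b=flow.phi_b, phi_L=flow.phi_L,
        vessel_weight=flow.vessel_weight, region_map=flow.region_map,
        node_pressures=flow.node_pressures,
    )


def save_trajectory_npz(trajectory: Trajectory, outdir: str | Path,
                        prefix: str = "conc") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for state in trajectory.states:
        p = outdir / f"{prefix}_t{int(round(state.t)):06d}.npz"
        np.savez(p, t=state.t, C_i=state.C_i, C_e=state.C_e, C_m=state.C_m)
        paths.append(p)
    return paths


def write_vtk_structured(path: str | Path, fields: dict[str, np.ndarray],
                         dx: float, dy: float) -> None:
    """Legacy ASCII VTK STRUCTURED_POINTS file with cell-centered scalars.

    Rows are flipped so the file's +y axis matches physical y (upward).
    """
    fields = {k: np.asarray(v, dtype=float) for k, v in fields.items()}
    shapes = {v.shape for v in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one grid shape")
    ny, nx = shapes.pop()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nperfusim fields\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"ORIGIN {dx / 2} {dy / 2} 0\n")
        fh.write(f"SPACING {dx} {dy} 1\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr[::-1, :].ravel()[None].T, fmt="%.10g")


def flow_summary(flow: FlowField) -> pd.DataFrame:
    rows = []
    for name, sel in (("tumor", flow.region_map), ("normal", ~flow.region_map)):
        rows.append({
            "region": name,
            "max_ifp_pa": float(flow.P_i[sel].max()),
            "median_ifp_pa": float(np.median(flow.P_i[sel])),
            "max_ifv_m_per_s": float(flow.speed[sel].max()),
            "median_ifv_m_per_s": float(np.median(flow.speed[sel])),
        })
    return pd.DataFrame(rows)
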