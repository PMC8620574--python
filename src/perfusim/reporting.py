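"""Reporting surfaces: region statistics, probe TACs, normalized maps."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .transport import Trajectory
from .types import ConcState, DomainSpec, FlowField, ProbeSpec

_COMPARTMENTS = ("C_i", "C_e", "C_m", "C_total")


def region_stats(trajectory: Trajectory, region_map: np.ndarray,
                 times=None) -> pd.DataFrame:
    """Median and mean of each compartment per region and time point.

    ``C_total`` is computed as the sum of the three compartments cell by
    cell, so the identity median-of-sum != sum-of-medians is preserved as in
    the source fields.
    """
    if times is None:
        times = trajectory.times
    rows = []
    for t in times:
        state = trajectory.at(t)
        for region_name, sel in (("tumor", region_map), ("normal", ~region_map)):
            row = {"time_s": t, "region": region_name}
            for comp in _COMPARTMENTS:
                vals = getattr(state, comp)[sel]
                row[f"median_{comp}"] = float(np.median(vals))
                row[f"mean_{comp}"] = float(np.mean(vals))
            rows.append(row)
    return pd.DataFrame(rows)


def _interpolator(domain: DomainSpec, grid: np.ndarray) -> RegularGridInterpolator:
    ny, nx = grid.shape
    x = (np.arange(nx) + 0.5) * (domain.width / nx)
    y_desc = domain.height - (np.arange(ny) + 0.5) * (domain.height / ny)
    # RegularGridInterpolator wants ascending axes: flip rows
    return RegularGridInterpolator(
        (y_desc[::-1], x), grid[::-1, :], bounds_error=False, fill_value=None
    )


def _check_inside(domain: DomainSpec, x: float, y: float, label: str) -> None:
    if not (0.0 <= x <= domain.width and 0.0 <= y <= domain.height):
        raise ValueError(f"probe {label!r} at ({x}, {y}) lies outside the domain")


def probe_tac(trajectory: Trajectory, probes: ProbeSpec,
              domain: DomainSpec) -> pd.DataFrame:
    """Bilinear point samples and cutline means of every compartment."""
    for label, x, y in probes.points:
        _check_inside(domain, x, y, label)
    for label, p0, p1, _n in probes.cutlines:
        _check_inside(domain, *p0, label)
        _check_inside(domain, *p1, label)
    rows = []
    for state in trajectory.states:
        interps = {c: _interpolator(domain, getattr(state, c)) for c in _COMPARTMENTS}
        for label, x, y in probes.points:
            row = {"probe": label, "kind": "point", "time_s": state.t}
            for comp in _COMPARTMENTS:
                row[comp] = float(interps[comp]([[y, x]])[0])
            rows.append(row)
        for label, (x0, y0), (x1, y1), n in probes.cutlines:
            t = np.linspace(0.0, 1.0, n)
            pts = np.column_stack([y0 + t * (y1 - y0), x0 + t * (x1 - x0)])
            row = {"probe": label, "kind": "cutline", "time_s": state.t}
            for comp in _COMPARTMENTS:
                row[comp] = float(np.mean(interps[comp](pts)))
            rows.append(row)
    return pd.DataFrame(rows)


def normalized_maps(trajectory: Trajectory) -> dict[float, dict[str, np.ndarray]]:
    """Each compartment normalized by the global max of C_total.

    Values lie in [0, 1]; the maximizing cell of C_total maps to exactly 1.
    """
    if not trajectory.states:
        raise ValueError("trajectory is empty")
    global_max = max(float(s.C_total.max()) for s in trajectory.states)
    if global_max <= 0.0:
        raise ValueError("all-zero trajectory cannot be normalized")
    out: dict[float, dict[str, np.ndarray]] = {}
    for state in trajectory.states:
        out[state.t] = {c: getattr(state, c) / global_max for c in _COMPARTMENTS}
    return out


def default_probes(flow: FlowField, smooth_sigma: float = 2.0) -> ProbeSpec:
    """Six probes ranked by local vessel density: high/low MVD pairs in the
    tumor, near the tumor rim, and far from it."""
    domain = flow.domain
    ny, nx = flow.vessel_weight.shape
    dx = domain.width / nx
    dy = domain.height / ny
    w = gaussian_filter(flow.vessel_weight, smooth_sigma)
    x = (np.arange(nx) + 0.5) * dx
    y = domain.height - (np.arange(ny) + 0.5) * dy
    xx, yy = np.meshgrid(x, y)
    cx, cy = domain.tumor_center
    rr = np.hypot(xx - cx, yy - cy)
    r_t = domain.tumor_radius
    zones = {
        "tumor": rr <= 0.8 * r_t,
        "peritumoral": (rr > 1.1 * r_t) & (rr <= 1.6 * r_t),
        "distant": rr > 2.2 * r_t,
    }
    points = []
    for zone_name, sel in zones.items():
        if not sel.any():
            continue
        wz = np.where(sel, w, np.nan)
        hi = np.unravel_index(np.nanargmax(wz), wz.shape)
        lo = np.unravel_index(np.nanargmin(wz), wz.shape)
        points.append((f"{zone_name}_high_mvd", float(xx[hi]), float(yy[hi])))
        points.append((f"{zone_name}_low_mvd", float(xx[lo]), float(yy[lo])))
    return ProbeSpec(points=points)
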