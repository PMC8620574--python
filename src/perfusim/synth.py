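"""Seeded synthetic capillary networks and rendered test images.

The generator stands in for an unavailable micrograph: four parent vessels
span the domain (top edge, bottom edge and two through the middle band) and
a stochastic branching process sprouts capillaries from them until target
vessel length densities are reached separately inside and outside the tumor
disc.  The algorithm is purely geometric — no mechanistic angiogenesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import BinaryMask, DomainSpec, RasterImage, VesselGraph


class GenerationError(RuntimeError):
    """Raised when the requested vessel densities cannot be realized."""


@dataclass
class NetworkSpec:
    """Targets and conventions for synthetic network generation.

    mvd_* are target capillary length densities in m of vessel per m^2 of
    tissue, counted over sprouted capillaries (parent vessels excluded).
    """

    mvd_tumor: float = 8000.0
    mvd_normal: float = 2500.0
    n_parent_vessels: int = 4
    parent_radius: float = 40e-6
    capillary_radius: float = 5e-6
    seed: int = 0
    step: float | None = None        # growth segment length; default domain-scaled
    branch_prob: float = 0.18
    angle_jitter: float = 0.55       # rad, std of direction perturbation per step

    def __post_init__(self) -> None:
        if self.mvd_tumor < 0 or self.mvd_normal < 0:
            raise ValueError("densities must be nonnegative")
        if self.parent_radius <= 0 or self.capillary_radius <= 0:
            raise ValueError("radii must be positive")


def _parent_rows(domain: DomainSpec, n: int) -> list[float]:
    """y-coordinates of horizontal parent vessels: near the top and bottom
    sides plus a middle pair.  Kept slightly inboard of the rectangle so the
    filtration sources do not sit on the outer pressure boundary (their
    endpoints still touch the left/right sides, which carry the blood
    pressure boundary conditions)."""
    h = domain.height
    if n == 4:
        return [0.05 * h, 0.45 * h, 0.55 * h, 0.95 * h]
    return list(np.linspace(0.05 * h, 0.95 * h, n))


def generate_network(domain: DomainSpec, spec: NetworkSpec) -> VesselGraph:
    """Grow a seeded random capillary network rooted in the parent vessels.

    Deterministic in (domain, spec): the same seed yields an identical graph.
    Realized sprouted-capillary length density lands within 10% of each
    region target (exactly zero when the target is zero).
    """
    rng = np.random.default_rng(spec.seed)
    step = spec.step if spec.step is not None else min(domain.width, domain.height) / 55.0

    nodes: list[tuple[float, float]] = []
    edges: list[tuple[int, int, float, float]] = []
    boundary: dict[int, float] = {}

    def add_node(x: float, y: float) -> int:
        nodes.append((float(x), float(y)))
        return len(nodes) - 1

    # --- parent vessels: horizontal, subdivided so sprouts attach at nodes
    n_sub = max(4, int(round(domain.width / step)))
    parent_node_ids: list[int] = []
    for y in _parent_rows(domain, spec.n_parent_vessels):
        xs = np.linspace(0.0, domain.width, n_sub + 1)
        ids = [add_node(x, y) for x in xs]
        for a, b in zip(ids[:-1], ids[1:]):
            ell = float(xs[1] - xs[0])
            edges.append((a, b, spec.parent_radius, ell))
        boundary[ids[0]] = np.nan   # placeholders; pressures assigned by caller
        boundary[ids[-1]] = np.nan
        parent_node_ids.extend(ids)
    n_parent_edges = len(edges)

    cx, cy = domain.tumor_center
    r_t = domain.tumor_radius

    def in_tumor(x: float, y: float) -> bool:
        return (x - cx) ** 2 + (y - cy) ** 2 <= r_t**2

    area_tumor = np.pi * r_t**2
    area_normal = domain.width * domain.height - area_tumor
    target = {
        "tumor": spec.mvd_tumor * area_tumor,
        "normal": spec.mvd_normal * area_normal,
    }
    realized = {"tumor": 0.0, "normal": 0.0}

    def saturated(region: str) -> bool:
        return realized[region] >= target[region] - 1e-12

    if target["tumor"] <= 0 and target["normal"] <= 0:
        return VesselGraph(
            np.asarray(nodes), edges, boundary,
            meta={"n_parent_edges": n_parent_edges, "realized_length": dict(realized)},
        )

    # --- stochastic sprouting
    # tips: (node_id, direction_angle)
    tips: list[tuple[int, float]] = []

    def seed_tips(k: int) -> None:
        for _ in range(k):
            nid = int(rng.choice(parent_node_ids))
            ang = rng.uniform(0.0, 2.0 * np.pi)
            tips.append((nid, ang))

    seed_tips(48)
    max_rounds = 400_000
    reseeds = 0
    rounds = 0
    while not (saturated("tumor") and saturated("normal")):
        rounds += 1
        if rounds > max_rounds:
            raise GenerationError(
                f"density targets unreachable: realized {realized}, target {target}"
            )
        if not tips:
            reseeds += 1
            if reseeds > 200:
                raise GenerationError(
                    f"generation stalled: realized {realized}, target {target}"
                )
            seed_tips(48)
            continue
        idx = int(rng.integers(len(tips)))
        nid, ang = tips.pop(idx)
        x0, y0 = nodes[nid]
        ang = ang + rng.normal(0.0, spec.angle_jitter)
        x1 = x0 + step * np.cos(ang)
        y1 = y0 + step * np.sin(ang)
        if not (0.0 <= x1 <= domain.width and 0.0 <= y1 <= domain.height):
            continue  # tip dies at the boundary
        region = "tumor" if in_tumor((x0 + x1) / 2.0, (y0 + y1) / 2.0) else "normal"
        if saturated(region):
            continue  # stop densifying a region that met its target
        new_id = add_node(x1, y1)
        edges.append((nid, new_id, spec.capillary_radius, step))
        realized[region] += step
        tips.append((new_id, ang))
        if rng.uniform() < spec.branch_prob:
            side = 1.0 if rng.uniform() < 0.5 else -1.0
            tips.append((new_id, ang + side * rng.uniform(0.6, 1.4)))

    for region in ("tumor", "normal"):
        if target[region] > 0:
            rel = abs(realized[region] - target[region]) / target[region]
            if rel > 0.10:
                raise GenerationError(
                    f"{region} density off target by {rel:.1%}"
                )

    return VesselGraph(
        np.asarray(nodes), edges, boundary,
        meta={"n_parent_edges": n_parent_edges, "realized_length": dict(realized)},
    )


# ---------------------------------------------------------------------------
# rasterization and rendering
# ---------------------------------------------------------------------------

def capillary_subgraph(graph: VesselGraph) -> VesselGraph:
    """The exchanging part of a generated network: all non-parent edges.

    Parent vessels are arteriole-scale feeders whose walls do not take part
    in Starling exchange; only the sprouted capillaries act as filtration
    sources.  Graphs without generator metadata are returned unchanged.
    """
    n_par = graph.meta.get("n_parent_edges", 0)
    if n_par == 0:
        return graph
    return VesselGraph(graph.nodes.copy(), list(graph.edges[n_par:]), {},
                       meta=dict(graph.meta))


def rasterize(
    graph: VesselGraph,
    pixel_size: float,
    width: float | None = None,
    height: float | None = None,
) -> BinaryMask:
    """Draw every edge as a stadium (capsule) of its radius onto a grid.

    The grid covers [0, width] x [0, height]; when omitted these default to
    the graph's bounding box.  Radii thinner than the pixel size trigger a
    warning and are drawn at least one pixel wide.
    """
    if graph.is_empty():
        if width is None or height is None:
            raise ValueError("empty graph requires explicit width/height")
        h_px = max(1, int(round(height / pixel_size)))
        w_px = max(1, int(round(width / pixel_size)))
        return BinaryMask(np.zeros((h_px, w_px), dtype=bool), pixel_size)

    if width is None:
        width = float(graph.nodes[:, 0].max()) + pixel_size
    if height is None:
        height = float(graph.nodes[:, 1].max()) + pixel_size
    h_px = max(1, int(round(height / pixel_size)))
    w_px = max(1, int(round(width / pixel_size)))
    mask = np.zeros((h_px, w_px), dtype=bool)

    min_r = min(e[2] for e in graph.edges)
    if pixel_size > min_r:
        warnings.warn(
            "pixel_size exceeds the smallest vessel radius; thin vessels are "
            "rasterized one pixel wide",
            stacklevel=2,
        )

    for (u, v, r, _ell) in graph.edges:
        x0, y0 = graph.nodes[u]
        x1, y1 = graph.nodes[v]
        r_draw = max(r, pixel_size / 2.0)
        # bounding box in pixel indices (row 0 = top)
        jmin = max(0, int((min(x0, x1) - r_draw) / pixel_size) - 1)
        jmax = min(w_px - 1, int((max(x0, x1) + r_draw) / pixel_size) + 1)
        imin = max(0, int((height - max(y0, y1) - r_draw) / pixel_size) - 1)
        imax = min(h_px - 1, int((height - min(y0, y1) + r_draw) / pixel_size) + 1)
        if jmin > jmax or imin > imax:
            continue
        jj = np.arange(jmin, jmax + 1)
        ii = np.arange(imin, imax + 1)
        xg = (jj + 0.5) * pixel_size
        yg = height - (ii + 0.5) * pixel_size
        xx, yy = np.meshgrid(xg, yg)
        dx, dy = x1 - x0, y1 - y0
        seg2 = dx * dx + dy * dy
        if seg2 == 0.0:
            dist = np.hypot(xx - x0, yy - y0)
        else:
            t = np.clip(((xx - x0) * dx + (yy - y0) * dy) / seg2, 0.0, 1.0)
            dist = np.hypot(xx - (x0 + t * dx), yy - (y0 + t * dy))
        mask[imin:imax + 1, jmin:jmax + 1] |= dist <= r_draw
    return BinaryMask(mask, pixel_size)


def render_image(
    mask: BinaryMask,
    noise_sigma: float = 0.0,
    background_level: float = 0.0,
    seed: int = 0,
) -> RasterImage:
    """Render a mask as a color micrograph-like image.

    Vessels are bright in the green channel (255) over ``background_level``;
    seeded Gaussian noise of standard deviation ``noise_sigma`` is added to
    all channels and the result clipped to [0, 255].
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    green = np.where(mask.values, 255.0, float(background_level))
    red = np.full((h, w), float(background_level))
    blue = np.full((h, w), float(background_level))
    img = np.stack([red, green, blue], axis=-1)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 255.0).round().astype(np.uint8)
    return RasterImage(img, mask.pixel_size)


def assign_boundary_pressures(
    graph: VesselGraph, inlet_pa: float, outlet_pa: float
) -> VesselGraph:
    """Set parent-vessel terminal pressures: left ends = inlet, right = outlet.

    Pass ``inlet_pa == outlet_pa`` for a uniform capillary pressure.
    Modifies the graph in place and returns it.
    """
    if not graph.boundary_pressures:
        raise ValueError("graph has no boundary nodes")
    xs = graph.nodes[list(graph.boundary_pressures), 0]
    x_mid = (xs.min() + xs.max()) / 2.0
    for nid in list(graph.boundary_pressures):
        x = graph.nodes[nid, 0]
        graph.boundary_pressures[nid] = inlet_pa if x <= x_mid else outlet_pa
    return graph
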