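"""Capillary-network extraction from color images.

Pipeline: green channel -> contrast-limited adaptive histogram equalization
-> fixed threshold -> small-component removal.  The binary mask is then
vectorized into wall contours and reduced to a centerline graph whose edges
carry a radius estimated from the distance transform.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, measure, morphology

from .types import BinaryMask, RasterImage, VesselGraph


def extract_vessel_mask(
    image: RasterImage,
    clahe_clip: float = 0.01,
    clahe_tiles: tuple[int, int] = (8, 8),
    threshold: float | None = 0.5,
    min_component_px: int = 0,
    otsu: bool = False,
) -> BinaryMask:
    """Segment vessels from an RGB image.

    The green channel is equalized with CLAHE, rescaled to [0, 1] and
    thresholded; connected components smaller than ``min_component_px``
    are discarded as noise.

    Setting ``otsu=True`` replaces the fixed threshold with Otsu's method.
    This is an extension beyond the reference pipeline, which uses a
    manually chosen threshold.
    """
    if not isinstance(image, RasterImage):
        raise TypeError("extract_vessel_mask expects a RasterImage (RGB)")
    if not otsu:
        if threshold is None:
            raise ValueError("threshold is required unless otsu=True")
        if not (0.0 <= threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")

    green = image.pixels[:, :, 1].astype(float) / 255.0
    h, w = green.shape
    kernel = (max(1, h // clahe_tiles[0]), max(1, w // clahe_tiles[1]))
    if green.max() > green.min():
        enhanced = exposure.equalize_adapthist(
            green, kernel_size=kernel, clip_limit=clahe_clip
        )
    else:
        enhanced = green  # constant image: CLAHE is undefined, pass through
    # equalize_adapthist already returns values in [0, 1]
    if otsu:
        threshold = float(filters.threshold_otsu(enhanced))
    mask = enhanced > threshold
    if min_component_px > 0:
        # drop components with fewer than min_component_px pixels
        mask = morphology.remove_small_objects(mask,
                                               max_size=min_component_px - 1)
    return BinaryMask(mask, image.pixel_size)


def _chaikin(poly: np.ndarray, passes: int) -> np.ndarray:
    """Corner-cutting smoothing of a closed polygon (kept closed)."""
    for _ in range(passes):
        p = poly[:-1]
        q = np.roll(p, -1, axis=0)
        out = np.empty((2 * len(p), 2))
        out[0::2] = 0.75 * p + 0.25 * q
        out[1::2] = 0.25 * p + 0.75 * q
        poly = np.vstack([out, out[:1]])
    return poly


def trace_contours(mask: BinaryMask, smooth_passes: int = 2) -> list[np.ndarray]:
    """Closed boundary polygons of every foreground component (holes too).

    Returns a list of (K, 2) arrays of physical (x, y) vertices in meters;
    the first and last vertex of each polygon coincide.  A couple of
    corner-cutting passes remove the half-pixel staircase of the marching
    contour (which would otherwise bias perimeters high); pass
    ``smooth_passes=0`` for the raw pixel-level contour.
    """
    values = mask.values
    if not values.any():
        return []
    h = values.shape[0]
    # pad so components touching the frame still yield closed contours
    padded = np.pad(values.astype(float), 1, constant_values=0.0)
    polygons = []
    for contour in measure.find_contours(padded, 0.5):
        rows = contour[:, 0] - 1.0
        cols = contour[:, 1] - 1.0
        x = (cols + 0.5) * mask.pixel_size
        y = (h - rows - 0.5) * mask.pixel_size
        poly = np.column_stack([x, y])
        if not np.allclose(poly[0], poly[-1]):
            poly = np.vstack([poly, poly[0]])
        if smooth_passes > 0 and len(poly) > 4:
            poly = _chaikin(poly, smooth_passes)
        polygons.append(poly)
    return polygons


def polygon_area(poly: np.ndarray) -> float:
    """Absolute shoelace area of a closed polygon."""
    x, y = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1])) / 2.0)


def polygon_perimeter(poly: np.ndarray) -> float:
    return float(np.hypot(*np.diff(poly, axis=0).T).sum())


# ---------------------------------------------------------------------------
# skeleton -> graph
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeletonize_to_graph(mask: BinaryMask) -> VesselGraph:
    """Reduce a vessel mask to a centerline graph.

    Nodes sit at skeleton endpoints and branch points; each edge records the
    traced centerline length and the mean distance-transform radius along it.
    """
    values = mask.values
    if not values.any():
        return VesselGraph(np.empty((0, 2)), [])

    skel = morphology.skeletonize(values)
    dist = ndimage.distance_transform_edt(values)
    px = mask.pixel_size
    h = values.shape[0]

    coords = np.argwhere(skel)
    index = {(int(i), int(j)): k for k, (i, j) in enumerate(coords)}
    degree = np.zeros(len(coords), dtype=int)
    for (i, j), k in index.items():
        for di, dj in _NEIGHBORS:
            if (i + di, j + dj) in index:
                degree[k] += 1

    def to_xy(pix) -> tuple[float, float]:
        i, j = pix
        return ((j + 0.5) * px, (h - i - 0.5) * px)

    # junction pixels (deg >= 3) and endpoints (deg <= 1) become graph nodes;
    # adjacent junction pixels are merged into a single node so a Y-branch
    # yields exactly one degree-3 node
    node_img = np.zeros_like(skel)
    for (i, j), k in index.items():
        if degree[k] != 2:
            node_img[i, j] = True
    labels, n_clusters = ndimage.label(node_img, structure=np.ones((3, 3)))

    nodes: list[tuple[float, float]] = []
    cluster_pixel_count = np.zeros(n_clusters + 1, dtype=int)
    for c in range(1, n_clusters + 1):
        pix = np.argwhere(labels == c)
        cluster_pixel_count[c] = len(pix)
        nodes.append(to_xy(pix.mean(axis=0)))

    def cluster_of(pix) -> int:
        return int(labels[pix[0], pix[1]])  # 0 if chain pixel

    edges: list[tuple[int, int, float, float]] = []
    edge_end_pixels: list[tuple[tuple, tuple]] = []
    visited_segments: set[frozenset] = set()

    def neighbors(pix):
        i, j = pix
        return [(i + di, j + dj) for di, dj in _NEIGHBORS if (i + di, j + dj) in index]

    def step_len(a, b) -> float:
        return float(np.hypot(a[0] - b[0], a[1] - b[1])) * px

    node_pixels = [tuple(map(int, p)) for p in np.argwhere(node_img)]
    for start in node_pixels:
        for nxt in neighbors(start):
            seg_key = frozenset((start, nxt))
            if seg_key in visited_segments:
                continue
            visited_segments.add(seg_key)
            if cluster_of(nxt):
                if cluster_of(nxt) != cluster_of(start):
                    # directly adjacent junction clusters
                    u, v = cluster_of(start) - 1, cluster_of(nxt) - 1
                    radius = (dist[start] + dist[nxt]) / 2.0 * px
                    edges.append((u, v, max(radius, px / 2.0),
                                  step_len(start, nxt)))
                    edge_end_pixels.append((start, nxt))
                continue
            # trace along the degree-2 chain until the next junction/endpoint
            path = [start, nxt]
            prev, cur = start, nxt
            while not cluster_of(cur):
                nbrs = [p for p in neighbors(cur) if p != prev]
                if not nbrs:
                    break  # open chain end (shouldn't happen: deg-1 is a node)
                nbrs.sort(key=lambda p: step_len(cur, p))
                prev, cur = cur, nbrs[0]
                visited_segments.add(frozenset((prev, cur)))
                path.append(cur)
            if not cluster_of(cur):
                continue
            u, v = cluster_of(start) - 1, cluster_of(cur) - 1
            length = sum(step_len(a, b) for a, b in zip(path[:-1], path[1:]))
            radius = float(np.mean([dist[p] for p in path])) * px
            length = max(length, px)
            radius = max(radius, px / 2.0)
            # traced length may not undercut the node (centroid) distance
            d = np.hypot(nodes[u][0] - nodes[v][0], nodes[u][1] - nodes[v][1])
            length = max(length, d)
            if u == v and length <= 2 * px:
                continue  # degenerate self-loop inside a thick junction
            edges.append((u, v, radius, length))
            edge_end_pixels.append((start, path[-1]))

    # extend terminal edges to the vessel wall: the medial axis stops about
    # one radius short of the end of a vessel
    node_degree = np.zeros(len(nodes), dtype=int)
    for (u, v, _r, _l) in edges:
        node_degree[u] += 1
        node_degree[v] += 1
    for k, (u, v, r, ell) in enumerate(edges):
        p_start, p_end = edge_end_pixels[k]
        extra = 0.0
        if node_degree[u] == 1 and cluster_pixel_count[cluster_of(p_start)] == 1:
            extra += max(dist[p_start] - 0.5, 0.0) * px
        if node_degree[v] == 1 and cluster_pixel_count[cluster_of(p_end)] == 1:
            extra += max(dist[p_end] - 0.5, 0.0) * px
        if extra:
            edges[k] = (u, v, r, ell + extra)

    # a closed loop with no branch point has no node pixels; represent it by
    # promoting one of its pixels to a node
    remaining = {tuple(map(int, c)) for k, c in enumerate(coords) if degree[k] == 2}
    for e in visited_segments:
        remaining -= set(e)
    while remaining:
        start = next(iter(remaining))
        loop = [start]
        prev, cur = None, start
        while True:
            nbrs = [p for p in neighbors(cur) if p != prev]
            if not nbrs:
                break
            prev, cur = cur, nbrs[0]
            if cur == start:
                break
            loop.append(cur)
        remaining -= set(loop)
        if len(loop) < 3:
            continue
        nid = len(nodes)
        nodes.append(to_xy(start))
        length = sum(step_len(a, b) for a, b in zip(loop, loop[1:] + [start]))
        radius = float(np.mean([dist[p] for p in loop])) * px
        edges.append((nid, nid, max(radius, px / 2.0), max(length, px)))

    return VesselGraph(np.asarray(nodes, dtype=float).reshape(-1, 2), edges)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_mask_png(mask: BinaryMask, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.values.astype(np.uint8) * 255))


def save_contours_csv(polygons: list[np.ndarray], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["polygon_id", "vertex_index", "x_m", "y_m"])
        for pid, poly in enumerate(polygons):
            for k, (x, y) in enumerate(poly):
                writer.writerow([pid, k, repr(float(x)), repr(float(y))])


def save_graph_csv(graph: VesselGraph, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["u", "v", "x_u", "y_u", "x_v", "y_v", "radius_m", "length_m"])
        for (u, v, r, ell) in graph.edges:
            xu, yu = graph.nodes[u]
            xv, yv = graph.nodes[v]
            writer.writerow([u, v, repr(xu), repr(yu), repr(xv), repr(yv),
                             repr(float(r)), repr(float(ell))])


def save_graph_graphml(graph: VesselGraph, path: str | Path) -> None:
    import networkx as nx

    g = nx.MultiGraph()
    for n, (x, y) in enumerate(graph.nodes):
        g.add_node(n, x=float(x), y=float(y),
                   boundary_pressure=float(graph.boundary_pressures.get(n, np.nan)))
    for (u, v, r, ell) in graph.edges:
        g.add_edge(u, v, radius_m=float(r), length_m=float(ell))
    nx.write_graphml(g, str(path))
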