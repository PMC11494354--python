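"""Steady-state morphology metrics: area distributions, junction angles,
aspect ratios, mean-area scaling, and the Voronoi reference network.

All shape statistics here are dimensionless, so for a scale-free network they
are parameter independent; distributions of polygon area collapse onto a
single curve once rescaled by the mean area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .faces import Polygon, extract_polygons
from .network import LiquidNetwork
from .params import DomainBoundary

__all__ = [
    "AreaDistribution",
    "area_distribution",
    "aspect_ratio",
    "junction_angles",
    "mean_area_scaling",
    "voronoi_network",
]


@dataclass
class AreaDistribution:
    """Log-binned normalized histogram of polygon areas."""

    bin_edges: np.ndarray       # strictly increasing, µm²
    prob_mass: np.ndarray       # sums to 1
    mean_area: float            # µm²
    rescaled_areas: np.ndarray  # A / ⟨A⟩

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.bin_edges) > 0)


def area_distribution(polys: list[Polygon], n_bins: int = 20) -> AreaDistribution:
    """Distribution of face areas on logarithmic bins, plus rescaled areas."""
    if len(polys) == 0:
        raise ValueError("need at least one polygon")
    areas = np.array([p.area for p in polys])
    mean = float(areas.mean())
    lo, hi = areas.min(), areas.max()
    if lo == hi:
        edges = np.array([lo * 0.999, hi * 1.001])
    else:
        edges = np.geomspace(lo * 0.999, hi * 1.001, n_bins + 1)
    counts, edges = np.histogram(areas, bins=edges)
    mass = counts / counts.sum()
    return AreaDistribution(edges, mass, mean, areas / mean)


def aspect_ratio(poly: Polygon) -> float:
    """Shortest/longest dimension of the minimum-area oriented bounding box.

    1.0 for squares; √3/2 ≈ 0.866 for regular hexagons.
    """
    from shapely.geometry import Polygon as ShapelyPolygon

    sp = ShapelyPolygon(poly.xy)
    if sp.area <= 0 or not sp.is_valid:
        sp = sp.convex_hull
    rect = sp.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        raise ValueError("degenerate (collinear) polygon")
    xy = np.asarray(rect.exterior.coords)[:4]
    s1 = float(np.linalg.norm(xy[1] - xy[0]))
    s2 = float(np.linalg.norm(xy[2] - xy[1]))
    if max(s1, s2) == 0:
        raise ValueError("degenerate (collinear) polygon")
    return min(s1, s2) / max(s1, s2)


def junction_angles(net: LiquidNetwork, degrees: bool = True) -> np.ndarray:
    """Inter-edge angles at every interior degree-3 junction, pooled.

    The three angles at each junction sum to 360°, so the pooled mean is
    exactly 120° regardless of parameters — only the spread is informative.
    """
    out = []
    periodic = net.domain.kind == "periodic"
    ext = np.asarray(net.domain.extents) if periodic else None
    for i in net.node_ids():
        if net.boundary[i] or len(net.adj[i]) != 3:
            continue
        vecs = []
        for jn, _ in net.adj[i]:
            d = net.pos[jn] - net.pos[i]
            if periodic:
                d = d - np.round(d / ext) * ext
            L = np.linalg.norm(d)
            if L == 0:
                break
            vecs.append(d / L)
        else:
            th = np.sort([math.atan2(v[1], v[0]) for v in vecs])
            gaps = np.diff(np.concatenate([th, [th[0] + 2 * math.pi]]))
            out.extend(gaps)
    ang = np.asarray(out)
    return np.degrees(ang) if degrees else ang


def mean_area_scaling(records: list[tuple[float, float, float]]) -> float:
    """Zero-intercept least-squares slope of ⟨A⟩ against b/k.

    ``records`` holds (b, k, mean_area) triples from independent steady-state
    runs; the slope is the dimensionless density coefficient γ relating mean
    polygon area to the squared length scale ℓ² = b/k.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 (b, k, mean-area) records")
    x = np.array([b / k for b, k, _ in records])
    y = np.array([a for _, _, a in records])
    if x.max() / x.min() < 10:
        raise ValueError("parameter span of b/k must be at least 10-fold")
    return float((x @ y) / (x @ x))


def voronoi_network(
    n_seeds: int,
    domain: DomainBoundary,
    rng: np.random.Generator,
) -> LiquidNetwork:
    """Voronoi tessellation of uniform random seeds, as a liquid-network graph.

    Serves as a reference ensemble: its normalized area distribution is much
    narrower and more sharply peaked than a liquid network's.  Cells are
    clipped to the domain; nodes on the clip boundary are flagged immobile.
    Junctions are degree 3 generically.
    """
    from scipy.spatial import Voronoi
    from shapely.geometry import Point, Polygon as ShapelyPolygon, box

    if n_seeds < 3:
        raise ValueError("need at least 3 seeds")
    if domain.kind == "circle":
        R = domain.radius
        pts = []
        while len(pts) < n_seeds:
            q = rng.uniform(-R, R, size=2)
            if q @ q < R * R:
                pts.append(q)
        seeds = np.asarray(pts)
        clip = Point(0, 0).buffer(R, quad_segs=128)
        far = 4 * R
    else:
        ex, ey = domain.extents
        seeds = rng.uniform((0, 0), (ex, ey), size=(n_seeds, 2))
        clip = box(0, 0, ex, ey)
        far = 4 * max(ex, ey)
    # distant ring of phantom seeds bounds every real cell
    th = np.linspace(0, 2 * math.pi, 64, endpoint=False)
    phantom = far * np.stack([np.cos(th), np.sin(th)], axis=1)
    if domain.kind != "circle":
        phantom += np.asarray(clip.centroid.coords[0])
    vor = Voronoi(np.vstack([seeds, phantom]))

    net = LiquidNetwork(domain if domain.kind == "circle" else
                        DomainBoundary("none", extents=getattr(domain, "extents", (1, 1))))
    key2id: dict[tuple, int] = {}

    def node_of(xy, on_boundary):
        kk = (round(float(xy[0]), 9), round(float(xy[1]), 9))
        if kk not in key2id:
            key2id[kk] = net.add_node(np.asarray(xy, float),
                                      boundary=bool(on_boundary))
        return key2id[kk]

    bnd = clip.exterior
    seen_edges = set()
    for s in range(n_seeds):
        region = vor.regions[vor.point_region[s]]
        if -1 in region or len(region) < 3:
            continue
        cell = ShapelyPolygon(vor.vertices[region]).intersection(clip)
        if cell.is_empty or cell.geom_type != "Polygon":
            continue
        coords = np.asarray(cell.exterior.coords)[:-1]
        n = len(coords)
        for t in range(n):
            a, b = coords[t], coords[(t + 1) % n]
            ka = (round(float(a[0]), 9), round(float(a[1]), 9))
            kb = (round(float(b[0]), 9), round(float(b[1]), 9))
            ekey = (min(ka, kb), max(ka, kb))
            if ekey in seen_edges:
                continue
            seen_edges.add(ekey)
            ia = node_of(a, bnd.distance(Point(a)) < 1e-7)
            ib = node_of(b, bnd.distance(Point(b)) < 1e-7)
            if ia != ib and net.parallel_count(ia, ib) == 0:
                net.add_edge(ia, ib)
    net.splice_or_prune(list(key2id.values()))
    return net
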