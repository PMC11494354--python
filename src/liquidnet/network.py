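"""Mutable planar spatial graph of junctions and tubules.

A :class:`LiquidNetwork` stores junction positions in flat numpy arrays with
alive-masks (slots are append-only and compacted on demand) plus a python
adjacency list for O(1) topological event handling.  Nodes are degree-3
junctions, except growing tips (degree 1), their bases (degree 3 counting the
dangling edge), and immobile rim nodes of a clipped domain.  Between any node
pair at most two parallel edges may exist ("doubly connected" pairs, i.e. 2-gon
loops); parallel edges carry a multiplicity tag 0/1 so the planar embedding can
tell them apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import segment_pairs_cross
from .params import DomainBoundary

__all__ = ["GrowingTip", "LiquidNetwork", "ValidationReport", "init_honeycomb",
           "network_length", "validate"]


@dataclass
class GrowingTip:
    """A growing tubule tip: degree-1 node advancing ballistically from its base."""

    tip_node: int
    base_node: int
    direction: np.ndarray  # unit 2-vector
    birth_time: float


class LiquidNetwork:
    """Planar liquid network: junction nodes, straight tubule edges, growing tips."""

    def __init__(self, domain: Optional[DomainBoundary] = None):
        self.domain = domain if domain is not None else DomainBoundary("none")
        cap = 64
        self.pos = np.zeros((cap, 2))
        self.node_alive = np.zeros(cap, bool)
        self.pinned = np.zeros(cap, bool)
        self.boundary = np.zeros(cap, bool)
        self.n_node_slots = 0
        self.edges = np.zeros((cap, 2), np.int64)
        self.edge_alive = np.zeros(cap, bool)
        self.edge_mult = np.zeros(cap, np.int8)
        self.n_edge_slots = 0
        self.adj: list[list[tuple[int, int]]] = []
        self.tips: list[GrowingTip] = []
        self.twogons: set[tuple[int, int]] = set()  # doubly-connected pairs
        self.time = 0.0

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return int(self.node_alive[: self.n_node_slots].sum())

    @property
    def n_edges(self) -> int:
        return int(self.edge_alive[: self.n_edge_slots].sum())

    def node_ids(self) -> np.ndarray:
        return np.flatnonzero(self.node_alive[: self.n_node_slots])

    def edge_ids(self) -> np.ndarray:
        return np.flatnonzero(self.edge_alive[: self.n_edge_slots])

    def degree(self, i: int) -> int:
        return len(self.adj[i])

    def neighbors(self, i: int) -> list[int]:
        return [j for j, _ in self.adj[i]]

    def _grow_nodes(self) -> None:
        cap = len(self.pos)
        self.pos = np.vstack([self.pos, np.zeros((cap, 2))])
        self.node_alive = np.concatenate([self.node_alive, np.zeros(cap, bool)])
        self.pinned = np.concatenate([self.pinned, np.zeros(cap, bool)])
        self.boundary = np.concatenate([self.boundary, np.zeros(cap, bool)])

    def _grow_edges(self) -> None:
        cap = len(self.edges)
        self.edges = np.vstack([self.edges, np.zeros((cap, 2), np.int64)])
        self.edge_alive = np.concatenate([self.edge_alive, np.zeros(cap, bool)])
        self.edge_mult = np.concatenate([self.edge_mult, np.zeros(cap, np.int8)])

    def add_node(self, xy, pinned: bool = False, boundary: bool = False) -> int:
        if self.n_node_slots >= len(self.pos):
            self._grow_nodes()
        i = self.n_node_slots
        self.n_node_slots += 1
        self.pos[i] = xy
        self.node_alive[i] = True
        self.pinned[i] = pinned
        self.boundary[i] = boundary
        self.adj.append([])
        return i

    def parallel_count(self, i: int, j: int) -> int:
        return sum(1 for n, _ in self.adj[i] if n == j)

    def add_edge(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("self-loop edges are not allowed")
        mult = self.parallel_count(i, j)
        if mult >= 2:
            raise ValueError(f"nodes {i},{j} are already doubly connected")
        if self.n_edge_slots >= len(self.edges):
            self._grow_edges()
        eid = self.n_edge_slots
        self.n_edge_slots += 1
        self.edges[eid] = (i, j)
        self.edge_alive[eid] = True
        self.edge_mult[eid] = mult
        self.adj[i].append((j, eid))
        self.adj[j].append((i, eid))
        if mult == 1:
            self.twogons.add((min(i, j), max(i, j)))
        return eid

    def remove_edge(self, eid: int) -> None:
        if not self.edge_alive[eid]:
            raise ValueError(f"edge {eid} is not alive")
        i, j = self.edges[eid]
        self.edge_alive[eid] = False
        self.adj[i] = [(n, e) for n, e in self.adj[i] if e != eid]
        self.adj[j] = [(n, e) for n, e in self.adj[j] if e != eid]
        # re-tag a surviving parallel edge so tags stay {0} or {0,1}
        self.twogons.discard((min(i, j), max(i, j)))
        for n, e in self.adj[i]:
            if n == j:
                self.edge_mult[e] = 0

    def remove_node(self, i: int) -> None:
        if self.adj[i]:
            raise ValueError(f"node {i} still has incident edges")
        self.node_alive[i] = False

    # -------------------------------------------------------------- geometry
    def edge_vectors(self, eids: Optional[np.ndarray] = None) -> np.ndarray:
        """Displacement node_a → node_b per edge (minimum image if periodic)."""
        if eids is None:
            eids = self.edge_ids()
        e = self.edges[eids]
        d = self.pos[e[:, 1]] - self.pos[e[:, 0]]
        if self.domain.kind == "periodic":
            ext = np.asarray(self.domain.extents)
            d -= np.round(d / ext) * ext
        return d

    def edge_lengths(self, eids: Optional[np.ndarray] = None) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors(eids), axis=1)

    def separation(self, i: int, j: int) -> float:
        d = self.pos[j] - self.pos[i]
        if self.domain.kind == "periodic":
            ext = np.asarray(self.domain.extents)
            d = d - np.round(d / ext) * ext
        return float(np.linalg.norm(d))

    def wrap(self, xy: np.ndarray) -> np.ndarray:
        if self.domain.kind == "periodic":
            return np.mod(xy, np.asarray(self.domain.extents))
        return xy

    # -------------------------------------------------------------- cleanup
    def splice_or_prune(self, seeds: Iterable[int]) -> None:
        """Restore the degree-3 invariant around the given nodes.

        Removes isolated nodes, prunes dangling non-tip chains, and splices out
        degree-2 nodes into a single straight edge.  Cascades to neighbors.
        Boundary nodes and live tip nodes are exempt.
        """
        tip_nodes = {t.tip_node for t in self.tips}
        queue = list(seeds)
        while queue:
            i = queue.pop()
            if not self.node_alive[i] or self.boundary[i] or i in tip_nodes:
                continue
            deg = len(self.adj[i])
            if deg == 0:
                self.node_alive[i] = False
            elif deg == 1:
                j, eid = self.adj[i][0]
                self.remove_edge(eid)
                self.node_alive[i] = False
                queue.append(j)
            elif deg == 2:
                (u, e1), (w, e2) = self.adj[i]
                self.remove_edge(e1)
                self.remove_edge(e2)
                self.node_alive[i] = False
                if u == w:
                    # degenerate loop collapsed onto one neighbor
                    queue.append(u)
                elif self.parallel_count(u, w) >= 2:
                    # splicing would create a triple edge: close the existing
                    # 2-gon (it is geometrically inside the vanished loop)
                    self.merge_doubly_connected(u, w)
                    queue.extend([u, w])
                else:
                    self.add_edge(u, w)

    def merge_doubly_connected(self, i: int, j: int) -> None:
        """Merge a doubly-connected pair (loop closure), then splice the remnant."""
        par = [e for n, e in self.adj[i] if n == j]
        if len(par) != 2:
            raise ValueError(f"nodes {i},{j} are not doubly connected")
        for e in par:
            self.remove_edge(e)
        if self.boundary[j] and not self.boundary[i]:
            i, j = j, i
        if not self.boundary[i]:
            self.pos[i] = self.pos[i] + 0.5 * (self.pos[j] - self.pos[i])
        # reattach j's remaining edges to i
        for n, e in list(self.adj[j]):
            self.remove_edge(e)
            if n != i and self.parallel_count(i, n) < 2:
                self.add_edge(i, n)
        self.node_alive[j] = False
        self.pinned[i] = self.pinned[i] or self.pinned[j]
        self.splice_or_prune([i])

    # ------------------------------------------------------------- compaction
    def compact(self) -> "LiquidNetwork":
        """Return a copy with dense node/edge numbering (alive entries only)."""
        out = LiquidNetwork(self.domain)
        out.time = self.time
        nid = self.node_ids()
        remap = {int(old): idx for idx, old in enumerate(nid)}
        n = len(nid)
        out.pos = self.pos[nid].copy()
        out.node_alive = np.ones(n, bool)
        out.pinned = self.pinned[nid].copy()
        out.boundary = self.boundary[nid].copy()
        out.n_node_slots = n
        out.adj = [[] for _ in range(n)]
        eids = self.edge_ids()
        m = len(eids)
        out.edges = np.zeros((max(m, 1), 2), np.int64)
        out.edge_alive = np.ones(m, bool)
        out.edge_mult = np.zeros(max(m, 1), np.int8)
        out.n_edge_slots = m
        for new_e, e in enumerate(eids):
            i, j = (remap[int(x)] for x in self.edges[e])
            out.edges[new_e] = (i, j)
            out.edge_mult[new_e] = self.edge_mult[e]
            out.adj[i].append((j, new_e))
            out.adj[j].append((i, new_e))
            if out.edge_mult[new_e] == 1:
                out.twogons.add((min(i, j), max(i, j)))
        out.tips = [
            GrowingTip(remap[t.tip_node], remap[t.base_node],
                       t.direction.copy(), t.birth_time)
            for t in self.tips
        ]
        return out

    def copy(self) -> "LiquidNetwork":
        return self.compact()


# ---------------------------------------------------------------------- length
def network_length(net: LiquidNetwork) -> float:
    """Total Euclidean tubule length (including dangling tip edges), µm."""
    if net.n_edges == 0:
        return 0.0
    return float(net.edge_lengths().sum())


# ------------------------------------------------------------------ validation
@dataclass
class ValidationReport:
    ok: bool
    first_violation: str = ""
    n_nodes: int = 0
    n_edges: int = 0
    n_faces: int = 0
    euler_characteristic: int = 0

    def __bool__(self) -> bool:
        return self.ok


def validate(net: LiquidNetwork, check_planarity: bool = True,
             check_euler: bool = True) -> ValidationReport:
    """Check the structural invariants of a liquid network.

    Verifies finite in-domain coordinates, the degree rules (interior junctions
    degree 3, tips degree 1), the two-parallel-edges maximum, connectivity,
    planarity (no two edges properly crossing), and the Euler formula
    V − E + F = 2 (0 on a periodic torus), counting the outer face.

    Topological events always preserve planarity, but free junction motion may
    transiently thread edges through one another; pass ``check_planarity=False``
    (which also skips the embedding-dependent Euler count unless requested) to
    check only the motion-independent topology.
    """
    nid = net.node_ids()
    eids = net.edge_ids()
    rep = ValidationReport(True, "", len(nid), len(eids), 0, 0)

    def fail(msg: str) -> ValidationReport:
        rep.ok = False
        rep.first_violation = msg
        return rep

    if len(nid) == 0:
        return fail("empty network")
    P = net.pos[nid]
    if not np.all(np.isfinite(P)):
        return fail("non-finite coordinates")
    if net.domain.kind == "circle":
        # rim corners of the clipped union may overhang the nominal radius;
        # mobile nodes must stay within the rim
        r = np.linalg.norm(P, axis=1)
        bnd_r = r[net.boundary[nid]]
        rmax = max(net.domain.radius, float(bnd_r.max()) if len(bnd_r) else 0.0)
        mobile = ~net.boundary[nid]
        if np.any(r[mobile] > rmax * (1 + 1e-6) + 1e-9):
            return fail("node outside circular domain")

    tip_nodes = {t.tip_node for t in net.tips}
    for i in nid:
        deg = len(net.adj[i])
        if int(i) in tip_nodes:
            if deg != 1:
                return fail(f"tip node {i} has degree {deg} != 1")
        elif net.boundary[i]:
            if deg < 1:
                return fail(f"boundary node {i} is isolated")
        elif deg != 3:
            return fail(f"interior node {i} has degree {deg} != 3")

    for i in nid:
        counts: dict[int, int] = {}
        for n, _ in net.adj[i]:
            counts[n] = counts.get(n, 0) + 1
            if counts[n] > 2:
                return fail(f"nodes {i},{n} have >2 parallel edges")

    # connectivity
    if len(eids):
        e = net.edges[eids]
        remap = {int(v): idx for idx, v in enumerate(nid)}
        rows = np.array([remap[int(a)] for a in e[:, 0]])
        cols = np.array([remap[int(b)] for b in e[:, 1]])
        g = coo_matrix((np.ones(len(eids)), (rows, cols)), shape=(len(nid),) * 2)
        ncomp, _ = connected_components(g, directed=False)
        if ncomp != 1:
            return fail(f"network has {ncomp} connected components")

    if check_planarity and len(eids) > 1:
        pair = _find_crossing(net, eids)
        if pair is not None:
            return fail(f"edges {pair[0]} and {pair[1]} cross")

    if check_euler and check_planarity:
        from .faces import count_faces  # local import to avoid cycle

        F = count_faces(net)
        rep.n_faces = F
        rep.euler_characteristic = len(nid) - len(eids) + F
        expected = 0 if net.domain.kind == "periodic" else 2
        if rep.euler_characteristic != expected:
            return fail(
                f"Euler characteristic V-E+F = {rep.euler_characteristic} "
                f"!= {expected}"
            )
    return rep


def _find_crossing(net: LiquidNetwork, eids: np.ndarray):
    """Find one properly-crossing edge pair, or None (KD-tree filtered)."""
    from scipy.spatial import cKDTree

    e = net.edges[eids]
    a = net.pos[e[:, 0]]
    vec = net.edge_vectors(eids)
    mid = a + 0.5 * vec
    half = 0.5 * np.linalg.norm(vec, axis=1)
    rad = float(half.max()) if len(half) else 0.0
    tree = cKDTree(mid)
    cand = tree.query_pairs(2 * rad * 1.001 + 1e-12, output_type="ndarray")
    if len(cand) == 0:
        return None
    # skip pairs sharing an endpoint
    ea, eb = e[cand[:, 0]], e[cand[:, 1]]
    share = (
        (ea[:, 0] == eb[:, 0]) | (ea[:, 0] == eb[:, 1])
        | (ea[:, 1] == eb[:, 0]) | (ea[:, 1] == eb[:, 1])
    )
    cand = cand[~share]
    if len(cand) == 0:
        return None
    ea, eb = e[cand[:, 0]], e[cand[:, 1]]
    cross = segment_pairs_cross(
        net.pos[ea[:, 0]], net.pos[ea[:, 1]], net.pos[eb[:, 0]], net.pos[eb[:, 1]]
    )
    idx = np.flatnonzero(cross)
    if len(idx) == 0:
        return None
    c = cand[idx[0]]
    return int(eids[c[0]]), int(eids[c[1]])


# ----------------------------------------------------------------- honeycomb
def init_honeycomb(edge_length: float, domain: DomainBoundary) -> LiquidNetwork:
    """Construct a regular honeycomb lattice clipped to the domain.

    For a circular domain, lattice edges crossing the rim are cut at the circle
    and the cut points are joined by chord edges along the circle, forming a
    closed, permanently immobile boundary.  For ``kind="none"`` a free-edge
    rectangular patch of side ``domain.extents`` is built (no immobile rim; such
    a patch contracts under tension unless growth compensates).
    """
    lam = float(edge_length)
    if not lam > 0:
        raise ValueError("edge_length must be > 0")
    if domain.kind == "circle":
        R = domain.radius
        if R < lam * math.sqrt(3):
            raise ValueError("domain too small to contain one full hexagon")
        half = R + 3 * lam
        return _honeycomb_union(lam, domain, half)
    elif domain.kind == "none":
        ex, ey = domain.extents
        if min(ex, ey) < 2 * lam * math.sqrt(3):
            raise ValueError("domain too small to contain one full hexagon")
        half = max(ex, ey) / 2 + 3 * lam
        return _honeycomb_union(lam, domain, half)
    else:
        return _honeycomb_periodic(lam, domain)


def _hex_lattice(lam: float, half: float):
    """All hexagons of a triangular-center lattice covering [-half, half]²."""
    sq3 = math.sqrt(3.0)
    nq = int(math.ceil(half / (1.5 * lam))) + 2
    nr = int(math.ceil(half / (sq3 * lam))) + 2
    ang = np.arange(6) * (math.pi / 3.0)
    hexa = np.stack([lam * np.cos(ang), lam * np.sin(ang)], axis=1)
    centers = []
    for q in range(-nq, nq + 1):
        cx = 1.5 * lam * q
        for r in range(-nr, nr + 1):
            cy = sq3 * lam * (r + 0.5 * (q % 2))
            centers.append((cx, cy))
    return np.asarray(centers), hexa


def _honeycomb_union(lam: float, domain: DomainBoundary, half: float) -> LiquidNetwork:
    """Union of all hexagons whose center lies inside the domain.

    Perimeter nodes of the union are the clip boundary; for a circular domain
    they are flagged immobile, closing the network so the interior face count is
    ≈ (domain area)/((3√3/2)λ²).
    """
    centers, hexa = _hex_lattice(lam, half)
    if domain.kind == "circle":
        sel = np.linalg.norm(centers, axis=1) < domain.radius
    else:
        ex, ey = domain.extents
        sel = (np.abs(centers[:, 0]) < ex / 2) & (np.abs(centers[:, 1]) < ey / 2)
    if not sel.any():
        raise ValueError("domain too small to contain one full hexagon")

    def key(p):
        return (round(p[0] / lam, 6), round(p[1] / lam, 6))

    corners: dict[tuple, int] = {}
    pts: list[np.ndarray] = []
    edge_use: dict[tuple[int, int], int] = {}
    for c in centers[sel]:
        loop = hexa + c
        ids = []
        for p in loop:
            kk = key(p)
            if kk not in corners:
                corners[kk] = len(pts)
                pts.append(p)
            ids.append(corners[kk])
        for a in range(6):
            i, j = ids[a], ids[(a + 1) % 6]
            e = (min(i, j), max(i, j))
            edge_use[e] = edge_use.get(e, 0) + 1

    P = np.asarray(pts)
    net = LiquidNetwork(domain)
    on_rim = np.zeros(len(P), bool)
    for (i, j), use in edge_use.items():
        if use == 1:
            on_rim[i] = on_rim[j] = True
    flag = domain.kind == "circle"
    idmap = [
        net.add_node(P[i], boundary=bool(on_rim[i]) and flag)
        for i in range(len(P))
    ]
    for i, j in edge_use:
        net.add_edge(idmap[i], idmap[j])
    if not flag:
        # free patch: no immobile rim; splice perimeter degree-2 corners
        net.splice_or_prune(list(idmap))
    return net


def init_network_3d(*args, **kwargs):
    """Stub: three-dimensional liquid networks are not implemented.

    A 3D extension is not a straightforward generalization: growing tips in
    3D generically miss existing tubules, so fusion requires a finite contact
    radius within which a tip can capture a tubule.  That radius is an
    additional length scale (besides ℓ = sqrt(b/k)) which modulates pore size
    and density, changing the scaling structure of the model.  Only the
    planar model is provided here.
    """
    raise NotImplementedError(
        "3D liquid networks require a tip-capture contact radius (an "
        "additional length scale) and are outside this package's scope"
    )


def _honeycomb_periodic(lam: float, domain: DomainBoundary) -> LiquidNetwork:
    """Commensurate honeycomb wrapped onto a periodic rectangle."""
    sq3 = math.sqrt(3.0)
    ex, ey = domain.extents
    if min(ex, ey) < 2 * lam * sq3:
        raise ValueError("domain too small to contain one full hexagon")
    ncol = max(2, int(round(ex / (1.5 * lam))))
    if ncol % 2:  # honeycomb needs an even column count to wrap
        ncol += 1
    nrow = max(2, int(round(ey / (sq3 * lam))))
    sx, sy = ex / (1.5 * ncol), ey / (sq3 * nrow)

    centers, hexa = _hex_lattice(1.0, 0.0)  # unit template only for corners
    net = LiquidNetwork(domain)

    def key(p):
        return (round(p[0] % (1.5 * ncol), 6) % round(1.5 * ncol, 6),
                round(p[1] % (sq3 * nrow), 6) % round(sq3 * nrow, 6))

    corners: dict[tuple, int] = {}
    edges = set()
    for q in range(ncol):
        cx = 1.5 * q
        for r in range(nrow):
            cy = sq3 * (r + 0.5 * (q % 2))
            loop = hexa + (cx, cy)
            ids = []
            for p in loop:
                kk = key(p)
                if kk not in corners:
                    corners[kk] = net.add_node(
                        np.array([kk[0] * sx, kk[1] * sy]))
                ids.append(corners[kk])
            for a in range(6):
                i, j = ids[a], ids[(a + 1) % 6]
                if i != j:
                    edges.add((min(i, j), max(i, j)))
    for i, j in sorted(edges):
        net.add_edge(i, j)
    return net
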