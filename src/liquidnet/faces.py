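"""Planar face (polygon) extraction by angular half-edge traversal.

Each undirected edge contributes two directed half-edges.  At every node the
outgoing half-edges are sorted by angle; following, from an incoming half-edge,
the clockwise-next outgoing one traces every face of the embedding exactly
once, counterclockwise around interior faces.  The unique face with negative
signed area is the outer face (absent on a periodic torus).  Parallel edges of
a doubly-connected pair are disambiguated by bowing each an infinitesimal,
consistently-signed amount, so 2-gon faces are traversed correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import polygon_signed_area
from .network import LiquidNetwork

__all__ = ["Polygon", "count_faces", "face_loops", "extract_polygons"]

_TIE_BREAK = 1e-7  # rad, parallel-edge angular offset


@dataclass
class Polygon:
    """One internal face of the network with geometry-derived metrics."""

    node_ids: np.ndarray          # ordered vertex loop
    xy: np.ndarray                # vertex coordinates (unwrapped if periodic)
    area: float                   # µm²
    perimeter: float              # µm
    centroid: np.ndarray          # µm
    touches_rim: bool = False     # face bounded in part by domain-rim chords
    n_sides: int = 0

    @property
    def gap_size(self) -> float:
        """Approximate inscribed diameter d = 4A/P, µm."""
        return 4.0 * self.area / self.perimeter


class _HalfEdgeMesh:
    def __init__(self, net: LiquidNetwork, drop_dangling: bool):
        adj = {int(i): list(net.adj[i]) for i in net.node_ids()}
        if drop_dangling:
            tipless = {t.tip_node for t in net.tips}
            stack = [i for i, a in adj.items()
                     if len(a) <= 1 and not net.boundary[i]]
            dropped = set()
            while stack:
                i = stack.pop()
                if i in dropped or len(adj.get(i, ())) > 1:
                    continue
                dropped.add(i)
                for j, eid in adj.pop(i, []):
                    adj[j] = [(n, e) for n, e in adj[j] if e != eid]
                    if len(adj[j]) <= 1 and not net.boundary[j]:
                        stack.append(j)
            _ = tipless  # tips are degree-1 by construction and get dropped too

        self.net = net
        # half-edges: for each (i -> j) store reverse, and next in face traversal
        he_src, he_dst, he_eid = [], [], []
        he_of = {}  # (eid, src) -> half-edge index
        for i, neigh in adj.items():
            for j, eid in neigh:
                he_of[(eid, i)] = len(he_src)
                he_src.append(i)
                he_dst.append(j)
                he_eid.append(eid)
        self.he_src = np.asarray(he_src, dtype=np.int64)
        self.he_dst = np.asarray(he_dst, dtype=np.int64)
        self.he_eid = np.asarray(he_eid, dtype=np.int64)
        nh = len(he_src)
        self.next = np.full(nh, -1, dtype=np.int64)
        if nh == 0:
            return

        vec = net.pos[self.he_dst] - net.pos[self.he_src]
        if net.domain.kind == "periodic":
            ext = np.asarray(net.domain.extents)
            vec -= np.round(vec / ext) * ext
        ang = np.arctan2(vec[:, 1], vec[:, 0])
        mult = net.edge_mult[self.he_eid]
        par = np.array(
            [net.parallel_count(int(s), int(d)) > 1
             for s, d in zip(self.he_src, self.he_dst)]
        )
        sign = np.where((mult == 0) == (self.he_src < self.he_dst), 1.0, -1.0)
        ang = ang + np.where(par, _TIE_BREAK * sign, 0.0)

        # per-node angular order, then next(h) = cw-successor of reverse(h)
        order: dict[int, list[int]] = {}
        for h, s in enumerate(self.he_src):
            order.setdefault(int(s), []).append(h)
        for s, hs in order.items():
            hs.sort(key=lambda h: ang[h])
        pos_in_order = np.zeros(nh, dtype=np.int64)
        for hs in order.values():
            for idx, h in enumerate(hs):
                pos_in_order[h] = idx
        for h in range(nh):
            j = int(self.he_dst[h])
            rev = he_of[(int(self.he_eid[h]), j)]
            hs = order[j]
            self.next[h] = hs[(pos_in_order[rev] - 1) % len(hs)]

    def faces(self) -> list[np.ndarray]:
        """Cycles of half-edge indices, one per face of the embedding."""
        seen = np.zeros(len(self.he_src), bool)
        out = []
        for h0 in range(len(self.he_src)):
            if seen[h0]:
                continue
            loop = []
            h = h0
            while not seen[h]:
                seen[h] = True
                loop.append(h)
                h = int(self.next[h])
            out.append(np.asarray(loop))
        return out


def count_faces(net: LiquidNetwork) -> int:
    """Number of faces of the embedding (outer face included), for Euler checks."""
    if net.n_edges == 0:
        return 1
    return len(_HalfEdgeMesh(net, drop_dangling=False).faces())


def face_loops(net: LiquidNetwork, drop_dangling: bool = True):
    """All face vertex loops with signed areas.

    Returns list of (node_loop, xy, signed_area).  Interior faces are
    counterclockwise (positive); the outer face is negative.
    """
    mesh = _HalfEdgeMesh(net, drop_dangling)
    out = []
    pos = net.pos
    periodic = net.domain.kind == "periodic"
    ext = np.asarray(net.domain.extents) if periodic else None
    for loop in mesh.faces():
        nodes = mesh.he_src[loop]
        if periodic:
            deltas = pos[mesh.he_dst[loop]] - pos[nodes]
            deltas -= np.round(deltas / ext) * ext
            xy = pos[nodes[0]] + np.vstack(
                [np.zeros(2), np.cumsum(deltas[:-1], axis=0)]
            )
        else:
            xy = pos[nodes]
        out.append((nodes, xy, polygon_signed_area(xy)))
    return out


def extract_polygons(
    net: LiquidNetwork,
    min_area: float = 1e-12,
    drop_rim: bool = False,
) -> list[Polygon]:
    """Extract all internal faces as :class:`Polygon` objects.

    Dangling (tip) edges are ignored.  The outer face — the unique face of
    negative signed area — is excluded (no outer face exists on a torus).
    Transient zero-area 2-gon faces fall below ``min_area`` and are skipped.
    With ``drop_rim=True``, faces bounded in part by domain-rim chords (both
    endpoints boundary nodes) are skipped as well; these are artifacts of the
    clipped enclosure rather than bulk network polygons.
    """
    loops = face_loops(net, drop_dangling=True)
    periodic = net.domain.kind == "periodic"
    if not periodic and len(loops) > 1:
        outer = min(range(len(loops)), key=lambda i: loops[i][2])
        if loops[outer][2] >= 0:
            raise ValueError("no outer face found; is the input planar?")
        loops = [l for i, l in enumerate(loops) if i != outer]
    polys = []
    bnd = net.boundary
    for nodes, xy, area in loops:
        if area <= min_area:
            continue
        touches = False
        nb = bnd[nodes]
        if nb.any():
            touches = bool(np.any(nb & np.roll(nb, -1)))
        if drop_rim and touches:
            continue
        d = np.roll(xy, -1, axis=0) - xy
        seglen = np.linalg.norm(d, axis=1)
        perim = float(seglen.sum())
        cx = xy[:, 0]
        cy = xy[:, 1]
        x1, y1 = np.roll(cx, -1), np.roll(cy, -1)
        cross = cx * y1 - x1 * cy
        cen = np.array(
            [np.sum((cx + x1) * cross), np.sum((cy + y1) * cross)]
        ) / (6.0 * area)
        polys.append(
            Polygon(
                node_ids=nodes,
                xy=xy,
                area=float(area),
                perimeter=perim,
                centroid=cen,
                touches_rim=touches,
                n_sides=len(nodes),
            )
        )
    return polys
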