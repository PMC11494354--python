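"""Time evolution of the liquid network.

Junctions obey the overdamped Langevin equation dr/dt = −b∇f + √(2D)η, where
f(r_i) = Σ_j |r_i − r_j| is the total tubule length at junction i: every edge
pulls its endpoints together with a constant, length-independent tension, so a
junction's deterministic velocity is b times the sum of unit vectors toward its
neighbors.  Topological relaxation happens through T1 neighbor swaps between
near-contact junction pairs (applied only when they strictly shorten the local
edge length) and through closure of contracting 2-gon loops.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .geometry import segment_pairs_cross
from .network import LiquidNetwork, network_length
from .params import SimParams

__all__ = [
    "tension_velocity",
    "tension_velocities",
    "langevin_step",
    "attempt_t1",
    "close_loops",
    "simulate",
    "Trajectory",
]


def tension_velocity(net: LiquidNetwork, node_id: int, b: float) -> np.ndarray:
    """Deterministic tension velocity b·Σ û(i→j) of one junction, µm/s.

    Each incident edge (parallel edges separately) contributes a unit pull
    toward the neighbor; a zero-length edge contributes nothing.
    """
    v = np.zeros(2)
    for j, eid in net.adj[node_id]:
        d = net.pos[j] - net.pos[node_id]
        if net.domain.kind == "periodic":
            ext = np.asarray(net.domain.extents)
            d = d - np.round(d / ext) * ext
        L = np.linalg.norm(d)
        if L > 0:
            v += d / L
    return b * v


def tension_velocities(net: LiquidNetwork, b: float) -> np.ndarray:
    """Vectorized tension velocities for all node slots (dead slots zero)."""
    vel = np.zeros_like(net.pos)
    eids = net.edge_ids()
    if len(eids) == 0:
        return vel
    e = net.edges[eids]
    d = net.edge_vectors(eids)
    L = np.linalg.norm(d, axis=1)
    ok = L > 0
    u = np.zeros_like(d)
    u[ok] = d[ok] / L[ok, None]
    np.add.at(vel, e[:, 0], b * u)
    np.add.at(vel, e[:, 1], -b * u)
    return vel


def langevin_step(
    net: LiquidNetwork,
    params: SimParams,
    rng: np.random.Generator,
    check_crossings: bool = False,
) -> int:
    """One Euler–Maruyama step of the junction equations of motion.

    Pinned and boundary junctions (and ballistic tip nodes) do not move.  With
    ``check_crossings`` enabled, any move that would make an edge properly cross
    another is rejected for all nodes of the offending edges this step.  Returns
    the number of rejected nodes.  Advances ``net.time`` by dt.
    """
    dt = params.dt
    vel = tension_velocities(net, params.b)
    n = net.n_node_slots
    mobile = net.node_alive[:n] & ~net.pinned[:n] & ~net.boundary[:n]
    for t in net.tips:
        mobile[t.tip_node] = False
    disp = vel[:n] * dt
    if params.D > 0:
        disp += np.sqrt(2 * params.D * dt) * rng.standard_normal((n, 2))
    disp[~mobile] = 0.0

    rejected = 0
    if check_crossings:
        rejected = _reject_crossing_moves(net, disp)
    net.pos[:n] += disp
    if net.domain.kind == "periodic":
        net.pos[:n] = np.mod(net.pos[:n], np.asarray(net.domain.extents))
    net.time += dt
    return rejected


def _reject_crossing_moves(net: LiquidNetwork, disp: np.ndarray) -> int:
    """Zero out moves that would create a proper edge crossing.

    Iterates because reverting one node's move can itself induce a crossing
    with a neighbor that did move; full reversion restores the previous planar
    state, so the loop terminates.
    """
    from scipy.spatial import cKDTree

    eids = net.edge_ids()
    if len(eids) < 2:
        return 0
    e = net.edges[eids]
    newpos = net.pos[: len(disp)] + disp
    a, b = newpos[e[:, 0]], newpos[e[:, 1]]
    mid = 0.5 * (a + b)
    half = 0.5 * np.linalg.norm(b - a, axis=1)
    margin = float(np.abs(disp).max()) * 4 + 1e-12
    tree = cKDTree(mid)
    pairs = tree.query_pairs(2 * float(half.max()) + margin,
                             output_type="ndarray")
    if len(pairs) == 0:
        return 0
    ea, eb = e[pairs[:, 0]], e[pairs[:, 1]]
    share = (
        (ea[:, 0] == eb[:, 0]) | (ea[:, 0] == eb[:, 1])
        | (ea[:, 1] == eb[:, 0]) | (ea[:, 1] == eb[:, 1])
    )
    ea, eb = ea[~share], eb[~share]
    if len(ea) == 0:
        return 0
    # First pass: a node pressed against an edge keeps its tangential motion
    # (frictionless sliding along the obstruction); a node under conflicting
    # constraints, or still crossing after projection, is halted outright.
    rejected: set[int] = set()
    constraint: dict[int, np.ndarray] = {}
    for it in range(64):
        newpos = net.pos[: len(disp)] + disp
        cross = segment_pairs_cross(newpos[ea[:, 0]], newpos[ea[:, 1]],
                                    newpos[eb[:, 0]], newpos[eb[:, 1]])
        if not cross.any():
            break
        idx = np.flatnonzero(cross)
        for q in idx:
            for nodes, other in ((ea[q], eb[q]), (eb[q], ea[q])):
                t_dir = net.pos[other[1]] - net.pos[other[0]]
                nrm = np.linalg.norm(t_dir)
                t_dir = t_dir / nrm if nrm > 0 else t_dir
                for nd in nodes:
                    nd = int(nd)
                    if it == 0 and nd not in constraint:
                        constraint[nd] = t_dir
                        disp[nd] = (disp[nd] @ t_dir) * t_dir
                    else:
                        disp[nd] = 0.0
                    rejected.add(nd)
    return len(rejected)


class NullGuard:
    """Permissive crossing oracle: all candidate segments are allowed."""

    def crosses(self, p0, p1, ignore_nodes) -> bool:
        return False


class PlanarGuard:
    """Local crossing oracle for topological events.

    Built once per step from a KD-tree of node positions; answers whether a
    candidate segment would properly cross any existing edge near it.  A
    distance margin absorbs the small node motion events themselves cause.
    """

    def __init__(self, net: LiquidNetwork, margin: float):
        from scipy.spatial import cKDTree

        self.net = net
        nid = net.node_ids()
        self.ids = nid
        self.tree = cKDTree(net.pos[nid]) if len(nid) else None
        lens = net.edge_lengths()
        self.max_edge = float(lens.max()) if len(lens) else 0.0
        self.margin = margin

    def crosses(self, p0, p1, ignore_nodes: set[int]) -> bool:
        if self.tree is None:
            return False
        mid = 0.5 * (np.asarray(p0) + np.asarray(p1))
        r = 0.5 * float(np.linalg.norm(np.asarray(p1) - np.asarray(p0)))
        idx = self.tree.query_ball_point(
            mid, r + 0.5 * self.max_edge + self.margin)
        eids = set()
        for ii in idx:
            node = int(self.ids[ii])
            if not self.net.node_alive[node]:
                continue
            for _, e in self.net.adj[node]:
                eids.add(e)
        if not eids:
            return False
        e = self.net.edges[sorted(eids)]
        keep = ~(
            np.isin(e[:, 0], list(ignore_nodes))
            | np.isin(e[:, 1], list(ignore_nodes))
        )
        e = e[keep]
        if len(e) == 0:
            return False
        from .geometry import segments_cross

        return bool(segments_cross(p0, p1, self.net.pos[e[:, 0]],
                                   self.net.pos[e[:, 1]]).any())


def attempt_t1(net: LiquidNetwork, d_t1: float,
               guard: Optional[PlanarGuard] = None) -> int:
    """T1 neighbor swaps between connected degree-3 junction pairs within d_t1.

    For each pair of connected junctions closer than the contact threshold,
    the two alternative pairings of their four external neighbors are
    evaluated at the current (fixed) positions; the reconnection is applied
    only if it strictly reduces the total local edge length and introduces no
    local crossing.  At most one swap per pair per call.  Returns the number
    of swaps performed.
    """
    eids = net.edge_ids()
    if len(eids) == 0:
        return 0
    lens = net.edge_lengths(eids)
    cand = eids[lens < d_t1]
    if len(cand) == 0:
        return 0
    tip_nodes = {t.tip_node for t in net.tips}
    base_nodes = {t.base_node for t in net.tips}

    # vectorized pre-screen: gather each candidate's external quad and keep
    # only pairs for which some alternative pairing is strictly shorter
    quads = []
    for eid in cand:
        i, j = (int(x) for x in net.edges[eid])
        if net.boundary[i] or net.boundary[j]:
            continue
        if {i, j} & (tip_nodes | base_nodes):
            continue
        if net.parallel_count(i, j) != 1:
            continue  # 2-gons are handled by loop closure
        if len(net.adj[i]) != 3 or len(net.adj[j]) != 3:
            continue
        ext_i = [n for n, e in net.adj[i] if e != eid]
        ext_j = [n for n, e in net.adj[j] if e != eid]
        quads.append((eid, i, j, *ext_i, *ext_j))
    if not quads:
        return 0
    q = np.asarray(quads, dtype=np.int64)
    p = net.pos

    def seps(u_col, w_col):
        d = p[q[:, w_col]] - p[q[:, u_col]]
        if net.domain.kind == "periodic":
            ext = np.asarray(net.domain.extents)
            d = d - np.round(d / ext) * ext
        return np.sqrt((d * d).sum(1))

    ia, ib, jc, jd = seps(1, 3), seps(1, 4), seps(2, 5), seps(2, 6)
    ic, idn, jb = seps(1, 5), seps(1, 6), seps(2, 4)
    cur = ia + ib + jc + jd
    alt = np.minimum(ia + ic + jb + jd, ia + idn + jb + jc)
    promising = q[alt < cur - 1e-12]
    if len(promising) == 0:
        return 0
    if guard is None:
        guard = PlanarGuard(net, margin=2 * d_t1)
    swaps = 0
    for row in promising:
        eid, i, j = (int(x) for x in row[:3])
        if not net.edge_alive[eid]:
            continue
        if len(net.adj[i]) != 3 or len(net.adj[j]) != 3:
            continue
        if net.parallel_count(i, j) != 1:
            continue
        if _resolve_pair(net, i, j, eid, guard):
            swaps += 1
    return swaps


def _resolve_pair(net, i: int, j: int, eid: int, guard) -> bool:
    """Apply the strictly-length-reducing T1 swap to one near-contact pair."""
    ext_i = [(n, e) for n, e in net.adj[i] if e != eid]
    ext_j = [(n, e) for n, e in net.adj[j] if e != eid]
    if len(ext_i) != 2 or len(ext_j) != 2:
        return False
    (a, _), (bn, eb_) = ext_i
    (c, ec_), (dn, ed_) = ext_j

    def dist(u, w):
        return net.separation(u, w)

    cur = dist(i, a) + dist(i, bn) + dist(j, c) + dist(j, dn)
    # alt1: i:{a,c}, j:{b,d}    alt2: i:{a,d}, j:{b,c}
    alt1 = dist(i, a) + dist(i, c) + dist(j, bn) + dist(j, dn)
    alt2 = dist(i, a) + dist(i, dn) + dist(j, bn) + dist(j, c)
    best, moved, move_in = (alt1, ec_, c) if alt1 <= alt2 else (alt2, ed_, dn)
    if best >= cur - 1e-12:
        return False
    if net.parallel_count(j, bn) >= 2 or net.parallel_count(i, move_in) >= 2:
        return False
    if bn == j or move_in == i:
        return False
    # crossing guard: the two rewired edges against everything nearby (edges
    # sharing an endpoint with the tested segment cannot properly cross it)
    p = net.pos
    if guard.crosses(p[j], p[bn], {j, bn}) \
            or guard.crosses(p[i], p[move_in], {i, move_in}):
        return False
    if segment_pairs_cross(p[j][None], p[bn][None],
                           p[i][None], p[move_in][None])[0]:
        return False
    net.remove_edge(eb_)
    net.remove_edge(moved)
    net.add_edge(j, bn)
    net.add_edge(i, move_in)
    return True


def close_loops(net: LiquidNetwork, d_close: float,
                guard: Optional[PlanarGuard] = None) -> int:
    """Merge doubly-connected junction pairs closer than d_close (loop closure).

    A contracting 2-gon experiences twice the tension pulling its junctions
    together as apart; once its junctions meet, the pair is merged at the
    midpoint and the remnant degree-2 node is spliced into one straight edge.
    A merge whose resulting geometry would cross a nearby foreign edge is
    deferred to a later step.  Returns the number of closures.
    """
    deferred: set[tuple[int, int]] = set()
    closures = 0
    guard_local = guard
    while True:
        pair = None
        # the doubly-connected registry is maintained incrementally, so only
        # the (few) live 2-gons need checking
        for key in sorted(net.twogons):
            if key in deferred:
                continue
            i, j = key
            if not (net.node_alive[i] and net.node_alive[j]):
                continue
            if net.boundary[i] and net.boundary[j]:
                continue
            if net.separation(i, j) < d_close:
                pair = (i, j)
                break
        if pair is None:
            return closures
        if guard_local is None:
            guard_local = PlanarGuard(net, margin=2 * d_close)
        if not isinstance(guard_local, NullGuard) and \
                _merge_would_cross(net, *pair, guard_local):
            # a foreign edge threads the region the merged geometry would
            # sweep; defer this closure until the obstruction moves away
            deferred.add((min(pair), max(pair)))
            continue
        net.merge_doubly_connected(*pair)
        closures += 1


def _merge_would_cross(net: LiquidNetwork, i: int, j: int,
                       guard: PlanarGuard) -> bool:
    """Would merging pair (i,j) and splicing the remnant cross a foreign edge?"""
    ext = []
    for node, other in ((i, j), (j, i)):
        for n, _ in net.adj[node]:
            if n != other:
                ext.append(n)
    p = net.pos
    if net.boundary[j]:
        m = p[j]
    elif net.boundary[i]:
        m = p[i]
    else:
        m = 0.5 * (p[i] + p[j])
    ignore = {i, j}
    if len(ext) == 2 and ext[0] != ext[1]:
        n1, n2 = ext
        return guard.crosses(p[n1], p[n2], ignore | {n1, n2})
    return any(
        guard.crosses(m, p[n], ignore | {n}) for n in set(ext)
    )


@dataclass
class Trajectory:
    """Scalar time series plus periodic network snapshots from one simulation."""

    params: SimParams
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    lengths: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    n_edges: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    snapshot_times: list[float] = field(default_factory=list)
    snapshots: list[LiquidNetwork] = field(default_factory=list)
    events: Counter = field(default_factory=Counter)
    spawn_log: list[tuple[float, bool]] = field(default_factory=list)

    def scalars(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "length": self.lengths,
             "n_nodes": self.n_nodes, "n_edges": self.n_edges}
        )


def simulate(
    net: LiquidNetwork,
    params: SimParams,
    t_max: float,
    rng: Optional[np.random.Generator] = None,
    record_interval: Optional[float] = None,
    record_from: float = 0.0,
    scalar_stride: int = 1,
    observers: tuple[Callable[[LiquidNetwork, float], None], ...] = (),
    validate_every: int = 0,
    planarity: str = "free",
) -> Trajectory:
    """Run the liquid-network simulation loop for a duration t_max.

    Per step: Langevin motion → T1 swaps → loop closures → tubule
    spawning/growth and pin updates.  Snapshots (compacted copies) are recorded
    every ``record_interval`` of simulated time once ``record_from`` is reached;
    scalar series every ``scalar_stride`` steps.  Fully reproducible given
    ``params.seed`` (or an explicit ``rng``).  ``validate_every`` > 0 enables
    debug-mode invariant checking every that many steps.

    ``planarity`` selects how edge crossings are treated: ``"free"`` (default)
    permits transient pass-throughs, which tension resolves and which the
    steady-state statistics require; ``"events"`` additionally vetoes
    topological events whose new geometry would cross a nearby edge; and
    ``"strict"`` also rejects junction moves that would thread an edge
    (sliding tangentially along the obstruction instead).  Strict mode keeps
    the embedding exactly planar but jams flattened faces, measurably
    densifying the steady state.
    """
    from . import growth
    from .network import validate as _validate

    if planarity not in ("free", "events", "strict"):
        raise ValueError(f"unknown planarity mode {planarity!r}")
    p = params.resolved()
    if rng is None:
        rng = np.random.default_rng(p.seed)
    traj = Trajectory(params=p)
    times, lengths, nn, ne = [], [], [], []
    n_steps = int(np.ceil(t_max / p.dt))
    next_record = record_from if record_interval is not None else np.inf
    t0 = net.time
    null_guard = NullGuard()
    for step in range(n_steps):
        traj.events["move_rejected"] += langevin_step(
            net, p, rng, check_crossings=(planarity == "strict"))
        guard = (PlanarGuard(net, margin=2 * (p.d_t1 + p.d_close))
                 if planarity != "free" else null_guard)
        traj.events["t1"] += attempt_t1(net, p.d_t1, guard)
        traj.events["closure"] += close_loops(net, p.d_close, guard)
        growth.growth_step(net, p, rng, traj)
        if p.k_p > 0 or p.k_u > 0:
            growth.update_pins(net, p.k_p, p.k_u, p.dt, rng)
        if step % scalar_stride == 0:
            times.append(net.time)
            lengths.append(network_length(net))
            nn.append(net.n_nodes)
            ne.append(net.n_edges)
        if net.time - t0 >= next_record - 1e-9:
            traj.snapshot_times.append(net.time)
            traj.snapshots.append(net.compact())
            next_record += record_interval
        for obs in observers:
            obs(net, net.time)
        if validate_every and (step + 1) % validate_every == 0:
            rep = _validate(net, check_planarity=(planarity == "strict"))
            if not rep.ok:
                raise RuntimeError(
                    f"invariant violated at t={net.time:.4g}: {rep.first_violation}"
                )
    traj.times = np.asarray(times)
    traj.lengths = np.asarray(lengths)
    traj.n_nodes = np.asarray(nn, int)
    traj.n_edges = np.asarray(ne, int)
    return traj
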