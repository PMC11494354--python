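"""Stochastic tubule spawning, tip growth/fusion, catastrophe, and pinning.

New tubules nucleate from existing ones as a Poisson process with rate k per
unit network length.  In the default instantaneous mode (justified by v ≫ b),
the new tip is ray-cast across the enclosing polygon: it fuses with the first
edge it meets at distance d with the catastrophe survival probability
exp(−α·d/v), and otherwise retracts leaving the network untouched.  The finite
mode advances tips ballistically at speed v with per-step Poissonian
catastrophe, for validating the instantaneous approximation.

Pinning temporarily immobilizes junctions (tethering to cytoskeleton or
organelles): a global Poisson process of rate k_p pins a random free junction,
and each pin releases at rate k_u, so the stationary pin count is n_p = k_p/k_u.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .geometry import ray_segment_intersections
from .network import GrowingTip, LiquidNetwork
from .params import SimParams

__all__ = [
    "sample_spawn_events",
    "spawn_tubule",
    "grow_tip_instantaneous",
    "grow_tip_finite_step",
    "update_pins",
    "growth_step",
]

#: Half-width (rad) of the spawn-direction cone around the mother-edge normal.
#: New tubules grow perpendicular to their mother tubule (random side): the
#: mean-field growth term models each successful spawn as spanning the
#: distance between parallel edges of the enclosing cell, i.e. a transverse
#: crossing, and oblique nucleation would mostly cut off short-lived slivers.
SPAWN_CONE_HALF_WIDTH = 0.0


def sample_spawn_events(
    net: LiquidNetwork, k: float, dt: float, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Sample spawn events for one step: list of (edge id, arc fraction).

    The number of events is Poisson(k·L·dt) with L the current total length;
    each event lands uniformly along the network (edges weighted by length).
    Dangling tip edges are excluded as spawn substrates.
    """
    if k <= 0:
        return []
    eids = net.edge_ids()
    if len(eids) == 0:
        return []
    skip = {e for t in net.tips for _, e in net.adj[t.tip_node]}
    # edges of a doubly-connected pair are geometrically coincident (a closed
    # lens of zero width); they are no substrate for new tubules
    for i, j in net.twogons:
        skip.update(e for n, e in net.adj[i] if n == j)
    if skip:
        eids = np.array([e for e in eids if e not in skip])
        if len(eids) == 0:
            return []
    lens = net.edge_lengths(eids)
    L = float(lens.sum())
    n = rng.poisson(k * L * dt)
    if n == 0:
        return []
    cum = np.cumsum(lens)
    s = rng.uniform(0, L, size=n)
    idx = np.searchsorted(cum, s)
    frac = (s - (cum[idx] - lens[idx])) / lens[idx]
    return [(int(eids[i]), float(f)) for i, f in zip(idx, frac)]


def _spawn_direction(
    axis: np.ndarray,
    rng: np.random.Generator,
    half_width: float = SPAWN_CONE_HALF_WIDTH,
) -> np.ndarray:
    """Direction of a new tubule: the mother-edge normal, on a random side.

    With ``half_width`` > 0 the direction is jittered uniformly within that
    cone around the normal (for sensitivity analyses).
    """
    side = 1.0 if rng.random() < 0.5 else -1.0
    theta = math.pi / 2
    if half_width > 0:
        theta += rng.uniform(-half_width, half_width)
    c, s = math.cos(theta), math.sin(theta) * side
    return np.array([axis[0] * c - axis[1] * s, axis[0] * s + axis[1] * c])


def _first_hit(net: LiquidNetwork, origin, direction, exclude_eid: int):
    """First edge intersected by the ray; returns (eid, t, s) or None."""
    eids = net.edge_ids()
    eids = eids[eids != exclude_eid]
    if len(eids) == 0:
        return None
    e = net.edges[eids]
    a = net.pos[e[:, 0]]
    if net.domain.kind == "periodic":
        ext = np.asarray(net.domain.extents)
        vec = net.pos[e[:, 1]] - a
        vec -= np.round(vec / ext) * ext
        hits = []
        for dx in (-ext[0], 0.0, ext[0]):
            for dy in (-ext[1], 0.0, ext[1]):
                t, s = ray_segment_intersections(
                    origin, direction, a + (dx, dy), a + (dx, dy) + vec)
                j = int(np.argmin(t))
                if np.isfinite(t[j]):
                    hits.append((t[j], int(eids[j]), float(s[j])))
        if not hits:
            return None
        t_min, eid, s = min(hits)
        return eid, float(t_min), s
    b = net.pos[e[:, 1]]
    t, s = ray_segment_intersections(origin, direction, a, b)
    j = int(np.argmin(t))
    if not np.isfinite(t[j]):
        return None
    return int(eids[j]), float(t[j]), float(s[j])


def _split_edge(net: LiquidNetwork, eid: int, frac: float) -> int:
    """Split an edge at arc fraction, returning the new degree-2 node id."""
    i, j = (int(x) for x in net.edges[eid])
    vec = net.edge_vectors(np.array([eid]))[0]
    frac = min(max(frac, 1e-9), 1 - 1e-9)
    xy = net.wrap(net.pos[i] + frac * vec)
    bnd = bool(net.boundary[i] and net.boundary[j])
    node = net.add_node(xy, boundary=bnd)
    net.remove_edge(eid)
    net.add_edge(i, node)
    net.add_edge(node, j)
    return node


def spawn_tubule(
    net: LiquidNetwork, eid: int, frac: float, rng: np.random.Generator
) -> GrowingTip:
    """Split the mother edge with a new base junction and attach a zero-length tip."""
    vec = net.edge_vectors(np.array([eid]))[0]
    axis = vec / np.linalg.norm(vec)
    base = _split_edge(net, eid, frac)
    direction = _spawn_direction(axis, rng)
    tip = net.add_node(net.pos[base].copy())
    net.add_edge(base, tip)
    gt = GrowingTip(tip, base, direction, net.time)
    net.tips.append(gt)
    return gt


def grow_tip_instantaneous(
    net: LiquidNetwork,
    eid: int,
    frac: float,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[bool, float]:
    """Spawn-and-resolve in the instantaneous-growth approximation.

    Ray-casts from the spawn point to the first edge at distance d and fuses
    with survival probability exp(−α·d/v); a catastrophe or an escaping ray
    leaves the network exactly as before (retraction restores the pre-spawn
    state).  Returns (fused, d); d is NaN when the ray escapes.
    """
    i, j = (int(x) for x in net.edges[eid])
    vec = net.edge_vectors(np.array([eid]))[0]
    L = float(np.linalg.norm(vec))
    if L <= 0:
        return False, float("nan")
    axis = vec / L
    origin = net.pos[i] + frac * vec
    direction = _spawn_direction(axis, rng)
    hit = _first_hit(net, origin, direction, exclude_eid=eid)
    if hit is None:
        return False, float("nan")
    hit_eid, d, s = hit
    h0, h1 = (int(x) for x in net.edges[hit_eid])
    if (min(h0, h1), max(h0, h1)) in net.twogons:
        # the target is one side of a collapsed 2-gon lens; its coincident
        # sibling would thread the fusion node, so the tip retracts instead
        return False, float("nan")
    if params.alpha > 0 and rng.random() >= math.exp(-params.alpha * d / params.v):
        return False, d
    base = _split_edge(net, eid, frac)
    target = _split_edge(net, hit_eid, s)
    net.add_edge(base, target)
    return True, d


def grow_tip_finite_step(
    net: LiquidNetwork, tip: GrowingTip, params: SimParams,
    rng: np.random.Generator
) -> Optional[bool]:
    """Advance one finite-speed tip by v·dt; fuse on contact, retract on catastrophe.

    Returns True on fusion, False on retraction, None while still growing.
    """
    if params.alpha > 0 and rng.random() < 1 - math.exp(-params.alpha * params.dt):
        _retract(net, tip)
        return False
    old = net.pos[tip.tip_node].copy()
    new = old + params.v * params.dt * tip.direction
    base_edges = {e for _, e in net.adj[tip.base_node]}
    hit = _first_hit_segment(net, old, new, exclude=base_edges)
    if hit is not None:
        eid, s = hit
        target = _split_edge(net, eid, s)
        tipn = tip.tip_node
        for n, e in list(net.adj[tipn]):
            net.remove_edge(e)
        net.node_alive[tipn] = False
        net.tips.remove(tip)
        net.add_edge(tip.base_node, target)
        return True
    if net.domain.kind == "circle" and np.linalg.norm(new) > net.domain.radius:
        _retract(net, tip)
        return False
    net.pos[tip.tip_node] = net.wrap(new)
    return None


def _first_hit_segment(net, p0, p1, exclude):
    eids = np.array([e for e in net.edge_ids() if e not in exclude])
    if len(eids) == 0:
        return None
    d = p1 - p0
    L = np.linalg.norm(d)
    if L == 0:
        return None
    e = net.edges[eids]
    a = net.pos[e[:, 0]]
    vec = net.edge_vectors(eids)  # minimum image if periodic
    if net.domain.kind == "periodic":
        ext = np.asarray(net.domain.extents)
        hits = []
        for dx in (-ext[0], 0.0, ext[0]):
            for dy in (-ext[1], 0.0, ext[1]):
                t, s = ray_segment_intersections(
                    p0, d / L, a + (dx, dy), a + (dx, dy) + vec)
                t = np.where(t <= L + 1e-12, t, np.inf)
                j = int(np.argmin(t))
                if np.isfinite(t[j]):
                    hits.append((float(t[j]), int(eids[j]), float(s[j])))
        if not hits:
            return None
        _, eid, s = min(hits)
        return eid, s
    t, s = ray_segment_intersections(p0, d / L, a, a + vec)
    t = np.where(t <= L + 1e-12, t, np.inf)
    j = int(np.argmin(t))
    if not np.isfinite(t[j]):
        return None
    return int(eids[j]), float(s[j])


def _retract(net: LiquidNetwork, tip: GrowingTip) -> None:
    """Remove a tip and restore the pre-spawn local topology exactly."""
    tipn = tip.tip_node
    for _, e in list(net.adj[tipn]):
        net.remove_edge(e)
    net.node_alive[tipn] = False
    net.tips.remove(tip)
    base = tip.base_node
    if len(net.adj[base]) == 2:
        # splice the spawn base out unconditionally (it may sit on a rim
        # edge and carry the boundary flag, which the generic cleanup spares)
        (u, e1), (w, e2) = net.adj[base]
        if u != w and net.parallel_count(u, w) < 2:
            net.remove_edge(e1)
            net.remove_edge(e2)
            net.node_alive[base] = False
            net.add_edge(u, w)
            return
    net.splice_or_prune([base])


def update_pins(
    net: LiquidNetwork, k_p: float, k_u: float, dt: float,
    rng: np.random.Generator
) -> tuple[int, int]:
    """Pin/unpin junctions for one step; returns (pinned, unpinned) counts.

    Pinning is a *global* Poisson process of rate k_p choosing a random free
    junction (so n_p = k_p/k_u is the stationary pin count); each existing pin
    releases independently at rate k_u.  Boundary and tip nodes never
    participate.
    """
    n = net.n_node_slots
    alive = net.node_alive[:n]
    tipmask = np.zeros(n, bool)
    for t in net.tips:
        tipmask[[t.tip_node, t.base_node]] = True
    eligible = alive & ~net.boundary[:n] & ~tipmask
    unpin_count = 0
    if k_u > 0:
        pinned_ids = np.flatnonzero(eligible & net.pinned[:n])
        if len(pinned_ids):
            release = rng.random(len(pinned_ids)) < 1 - math.exp(-k_u * dt)
            net.pinned[pinned_ids[release]] = False
            unpin_count = int(release.sum())
    pin_count = 0
    if k_p > 0:
        n_events = rng.poisson(k_p * dt)
        if n_events:
            free_ids = np.flatnonzero(eligible & ~net.pinned[:n])
            take = min(n_events, len(free_ids))
            chosen = rng.choice(free_ids, size=take, replace=False)
            net.pinned[chosen] = True
            pin_count = int(take)
    return pin_count, unpin_count


def growth_step(net, params: SimParams, rng, traj=None) -> None:
    """Spawning plus tip growth for one simulation step (both growth modes)."""
    events = sample_spawn_events(net, params.k, params.dt, rng)
    for eid, frac in events:
        if not net.edge_alive[eid]:
            if traj is not None:
                traj.events["spawn_skipped"] += 1
            continue
        if params.growth_mode == "instant":
            fused, d = grow_tip_instantaneous(net, eid, frac, params, rng)
            if traj is not None:
                traj.events["fusion" if fused else "retraction"] += 1
                if np.isfinite(d):
                    traj.spawn_log.append((d, fused))
        else:
            spawn_tubule(net, eid, frac, rng)
            if traj is not None:
                traj.events["spawn"] += 1
    if params.growth_mode == "finite":
        for tip in list(net.tips):
            res = grow_tip_finite_step(net, tip, params, rng)
            if traj is not None and res is not None:
                traj.events["fusion" if res else "retraction"] += 1
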