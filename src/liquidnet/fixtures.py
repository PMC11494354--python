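"""Deterministic synthetic fixtures for testing the analysis operations.

These generators produce inputs with known ground truth — perturbed lattices,
polygon-track ensembles drawn from a prescribed growth law and splitting
hazard, and catastrophe outcome datasets — so every fitting operation can be
verified by parameter recovery without running the full simulator.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .faces import Polygon
from .meanfield import GrowthLaw
from .network import LiquidNetwork, init_honeycomb
from .params import DomainBoundary
from .rearrange import PolygonTrack
from .structure import voronoi_network

__all__ = ["make_fixture"]


def perturbed_honeycomb(edge_length: float, domain: DomainBoundary,
                        jitter: float, rng: np.random.Generator) -> LiquidNetwork:
    """Honeycomb with Gaussian node jitter (boundary nodes stay put)."""
    net = init_honeycomb(edge_length, domain)
    if jitter > 0:
        ids = net.node_ids()
        mobile = ids[~net.boundary[ids]]
        net.pos[mobile] += rng.normal(0.0, jitter, size=(len(mobile), 2))
    return net


def synthetic_tracks(
    law: GrowthLaw,
    khat: float,
    n_tracks: int,
    rng: np.random.Generator,
    mean_area: float = 1.0,
    tau: float = 1.0,
    dt_tau: float = 0.05,
    noise: float = 0.0,
    x0_range: tuple[float, float] = (0.05, 6.0),
    max_steps: int = 400,
) -> list[PolygonTrack]:
    """Polygon-area trajectories integrated from a growth law plus splitting.

    Areas follow the deterministic drift; each track terminates by closure
    (area → 0) or by a stochastic splitting event with hazard k̂·√x.
    Optional multiplicative measurement noise tests fit robustness.
    """
    tracks = []
    dt = dt_tau
    for tid in range(n_tracks):
        x = math.exp(rng.uniform(math.log(x0_range[0]), math.log(x0_range[1])))
        t = 0.0
        times, areas, cents = [], [], []
        for _ in range(max_steps):
            obs = x * (1.0 + noise * rng.standard_normal()) if noise else x
            times.append(t * tau)
            areas.append(max(obs, 1e-12) * mean_area)
            cents.append(np.zeros(2))
            if rng.random() < 1.0 - math.exp(-khat * math.sqrt(x) * dt):
                break  # split
            # midpoint integration of the drift
            k1 = float(law.rate(x))
            xm = max(x + 0.5 * dt * k1, 0.0)
            x = x + dt * float(law.rate(xm))
            t += dt
            if x <= 1e-6:
                break  # closed
        if len(times) >= 2:
            tracks.append(PolygonTrack(tid, times, areas, cents))
    return tracks


def synthetic_success_events(
    alpha: float, v: float, n: int, rng: np.random.Generator,
    gap_range: tuple[float, float] = (0.2, 6.0),
) -> list[tuple[float, bool]]:
    """(gap, fused) outcomes drawn from the survival law S(d) = e^(−αd/v)."""
    d = rng.uniform(*gap_range, size=n)
    fused = rng.random(n) < np.exp(-alpha * d / v)
    return list(zip(d.tolist(), fused.tolist()))


def drifting_polygon_frames(
    n_polys: int, n_frames: int, drift: float, rng: np.random.Generator,
    box: float = 20.0,
    min_sep: float = 0.0,
) -> tuple[list[list[Polygon]], list[float]]:
    """Frames of fake polygons drifting with known correspondence.

    Every polygon is a small square of fixed area whose centroid advances by
    a constant displacement of magnitude ``drift`` per frame.  With
    ``min_sep`` > 0 initial centroids keep at least that separation
    (rejection sampling), so trajectories cannot collide within
    ``min_sep/2 − n_frames·drift`` of each other.
    """
    cents_list: list[np.ndarray] = []
    tries = 0
    while len(cents_list) < n_polys:
        cand = rng.uniform(2, box - 2, size=2)
        if min_sep <= 0 or all(
            np.linalg.norm(cand - c) >= min_sep for c in cents_list
        ):
            cents_list.append(cand)
        tries += 1
        if tries > 100_000:
            raise RuntimeError("could not place polygons with min_sep")
    cents = np.asarray(cents_list)
    vels = rng.normal(size=(n_polys, 2))
    vels = drift * vels / np.linalg.norm(vels, axis=1, keepdims=True)
    frames = []
    times = []
    for f in range(n_frames):
        polys = []
        for pidx in range(n_polys):
            c = cents[pidx] + f * vels[pidx]
            h = 0.5
            xy = np.array([[c[0]-h, c[1]-h], [c[0]+h, c[1]-h],
                           [c[0]+h, c[1]+h], [c[0]-h, c[1]+h]])
            polys.append(Polygon(node_ids=np.arange(4), xy=xy, area=1.0,
                                 perimeter=4.0, centroid=c.copy(), n_sides=4))
        frames.append(polys)
        times.append(float(f))
    return frames, times


def make_fixture(kind: str, rng: np.random.Generator, **kw):
    """Dispatch fixture generation by kind (see module docstring)."""
    kinds = {
        "honeycomb": lambda: init_honeycomb(
            kw.get("edge_length", 1.0),
            kw.get("domain", DomainBoundary("circle", radius=10.0))),
        "perturbed-honeycomb": lambda: perturbed_honeycomb(
            kw.get("edge_length", 1.0),
            kw.get("domain", DomainBoundary("circle", radius=10.0)),
            kw.get("jitter", 0.05), rng),
        "voronoi": lambda: voronoi_network(
            kw.get("n_seeds", 100),
            kw.get("domain", DomainBoundary("circle", radius=10.0)), rng),
        "synthetic-tracks": lambda: synthetic_tracks(
            kw.get("law", GrowthLaw()), kw.get("khat", 0.9),
            kw.get("n_tracks", 500), rng, noise=kw.get("noise", 0.0)),
        "synthetic-success-events": lambda: synthetic_success_events(
            kw.get("alpha", 0.25), kw.get("v", 1.1), kw.get("n", 10000), rng),
    }
    if kind not in kinds:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"known: {', '.join(sorted(kinds))}")
    return kinds[kind]()
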