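"""Dynamics quantification: EMMD, relaxation-time fits, polygon tracking,
the polygon growth law, and the catastrophe success-rate fit.

The edge mean minimal distance (EMMD) measures how far the network has
rearranged from a reference configuration: both networks are meshed at fixed
arc-length spacing and, for every mesh point of the later network, the
distance to the nearest mesh point of the reference is averaged.  Polygon
tracking links faces across snapshots by their centroids (globally optimal
assignment per frame pair), yielding per-polygon area trajectories from which
the nondimensional growth law g·x^β − h·√x is fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .faces import Polygon
from .meanfield import GrowthLaw
from .network import LiquidNetwork

__all__ = [
    "network_mesh",
    "emmd",
    "fit_exponential_timescale",
    "PolygonTrack",
    "track_polygons",
    "fit_growth_law",
    "fit_success_rate",
]


def network_mesh(net: LiquidNetwork, spacing: float = 0.05) -> np.ndarray:
    """Dense point set sampled along all edges at fixed arc-length spacing.

    Every edge contributes at least its two endpoints.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    eids = net.edge_ids()
    if len(eids) == 0:
        raise ValueError("empty network")
    e = net.edges[eids]
    a = net.pos[e[:, 0]]
    vec = net.edge_vectors(eids)
    lens = np.linalg.norm(vec, axis=1)
    pts = [a, a + vec]
    for eidx in range(len(eids)):
        n_in = int(lens[eidx] // spacing)
        if n_in >= 1:
            t = (np.arange(1, n_in + 1) * spacing / lens[eidx])[:, None]
            pts.append(a[eidx] + t * vec[eidx])
    return np.vstack(pts)


def emmd(net_ref: LiquidNetwork, net_t: LiquidNetwork,
         spacing: float = 0.05) -> float:
    """Edge mean minimal distance from ``net_t`` to ``net_ref``, µm.

    Directional: mesh points of the later network are matched to the nearest
    mesh point of the reference, not vice versa.
    """
    ref = network_mesh(net_ref, spacing)
    cur = network_mesh(net_t, spacing)
    d, _ = cKDTree(ref).query(cur, workers=-1)
    return float(d.mean())


def fit_exponential_timescale(t: Sequence[float], y: Sequence[float]):
    """Fit y(t) = c·(1 − e^(−t/τ)) by nonlinear least squares.

    Returns (plateau c, timescale τ, rms residual).  Raises on degenerate
    input (fewer than 5 points, or a flat series with no identifiable
    timescale).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < 5:
        raise ValueError("need at least 5 points")
    if np.ptp(y) <= 1e-12 * max(1.0, abs(float(y.mean()))):
        raise ValueError("constant series: timescale is unidentifiable")

    def f(tt, c, tau):
        return c * (1.0 - np.exp(-tt / tau))

    c0 = float(y[-1]) if y[-1] != 0 else float(y.max())
    tau0 = float(t[len(t) // 3] - t[0] + 1e-9)
    popt, _ = optimize.curve_fit(
        f, t, y, p0=[c0, tau0],
        bounds=([-np.inf, 1e-12], [np.inf, np.inf]), maxfev=20000,
    )
    resid = float(np.sqrt(np.mean((f(t, *popt) - y) ** 2)))
    return float(popt[0]), float(popt[1]), resid


@dataclass
class PolygonTrack:
    """Area/centroid time series of one tracked polygon."""

    track_id: int
    times: list[float] = field(default_factory=list)
    areas: list[float] = field(default_factory=list)
    centroids: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.times)


def track_polygons(
    frames: Sequence[Sequence[Polygon]],
    times: Sequence[float],
    max_disp: float,
    memory: int = 0,
    split_frac: Optional[float] = None,
) -> list[PolygonTrack]:
    """Link polygons across frames by nearest centroids.

    Frame-to-frame assignment minimizes total centroid displacement (Hungarian
    algorithm) with a hard gate at ``max_disp``; a track not matched for up to
    ``memory`` consecutive frames may be re-acquired, after which it ends
    (polygon closed or split).

    With ``split_frac`` set, a track is additionally *terminated* when its
    area drops by more than that fraction between consecutive frames: a
    splitting event replaces one polygon by two, and centroid linking alone
    would silently continue on a daughter, inflating apparent lifetimes.
    The daughter then starts a new track.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    tracks: list[PolygonTrack] = []
    active: list[tuple[PolygonTrack, np.ndarray, int]] = []  # (track, last c, missed)
    next_id = 0
    for polys in frames[0:1]:
        for p in polys:
            tr = PolygonTrack(next_id, [times[0]], [p.area], [p.centroid])
            next_id += 1
            tracks.append(tr)
            active.append((tr, p.centroid, 0))

    for fi in range(1, len(frames)):
        polys = list(frames[fi])
        t = times[fi]
        if active and polys:
            last = np.array([c for _, c, _ in active])
            cur = np.array([p.centroid for p in polys])
            dist = np.linalg.norm(last[:, None, :] - cur[None, :, :], axis=2)
            big = 1e6
            cost = np.where(dist <= max_disp, dist, big)
            rows, cols = optimize.linear_sum_assignment(cost)
            matched_rows = set()
            matched_cols = set()
            for r, c in zip(rows, cols):
                if cost[r, c] >= big:
                    continue
                tr, _, _ = active[r]
                if split_frac is not None and tr.areas and \
                        polys[c].area < (1.0 - split_frac) * tr.areas[-1]:
                    continue  # abrupt shrink: a split; end here, daughter
                    # becomes a fresh track below
                tr.times.append(t)
                tr.areas.append(polys[c].area)
                tr.centroids.append(polys[c].centroid)
                matched_rows.add(r)
                matched_cols.add(c)
        else:
            matched_rows, matched_cols = set(), set()
        new_active = []
        for r, (tr, c, missed) in enumerate(active):
            if r in matched_rows:
                new_active.append((tr, tr.centroids[-1], 0))
            elif missed < memory:
                new_active.append((tr, c, missed + 1))
        for cidx, p in enumerate(polys):
            if cidx not in matched_cols:
                tr = PolygonTrack(next_id, [t], [p.area], [p.centroid])
                next_id += 1
                tracks.append(tr)
                new_active.append((tr, p.centroid, 0))
        active = new_active
    return tracks


def fit_growth_law(
    tracks: Sequence[PolygonTrack],
    mean_area: float,
    tau: float,
    n_bins: int = 10,
    x_range: tuple[float, float] = (0.1, 6.0),
    p0: tuple[float, float, float] = (1.7, 1.9, 0.78),
    max_frac_change: float = 0.3,
) -> GrowthLaw:
    """Fit the nondimensional polygon drift law g·x^β − h·√x to track data.

    Growth rates dA/dt are estimated by centered finite differences along each
    track, nondimensionalized by (τ/⟨A⟩), binned by x = A/⟨A⟩ (coarse log
    bins), and the bin means are fitted by SE-weighted least squares.  The
    law describes smooth tension-driven growth and shrinkage, so samples
    adjacent to a discontinuous area change (a splitting event or a tracking
    jump, flagged by a single-frame fractional change above
    ``max_frac_change``) are excluded.  The default fit range starts at
    x = 0.1: below that, polygon dynamics are dominated by the discrete
    closure mechanics (2-gon collapse) that the smooth drift ansatz does not
    describe.
    """
    xs, ys = [], []
    for tr in tracks:
        if len(tr) < 3:
            continue
        t = np.asarray(tr.times)
        a = np.asarray(tr.areas)
        frac = np.abs(np.diff(a)) / np.maximum(a[:-1], 1e-300)
        smooth = (frac[:-1] < max_frac_change) & (frac[1:] < max_frac_change)
        dadt = (a[2:] - a[:-2]) / (t[2:] - t[:-2])
        xs.append((a[1:-1] / mean_area)[smooth])
        ys.append((dadt * tau / mean_area)[smooth])
    if not xs:
        raise ValueError("no tracks long enough for centered differences")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    keep = (x > x_range[0]) & (x < x_range[1])
    x, y = x[keep], y[keep]
    if len(x) < 100:
        raise ValueError(f"only {len(x)} growth-rate samples; need >= 100")
    edges = np.geomspace(x_range[0], x_range[1], n_bins + 1)
    idx = np.digitize(x, edges) - 1
    bx, by, bw = [], [], []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n < 5:
            continue
        bx.append(float(np.exp(np.mean(np.log(x[sel])))))
        by.append(float(y[sel].mean()))
        bw.append(float(y[sel].std(ddof=1) / math.sqrt(n)) + 1e-9)
    bx, by, bw = (np.asarray(v) for v in (bx, by, bw))
    if bx.max() < 1.0 or bx.min() > 0.5:
        raise ValueError("binned data span too narrow around x = 1")

    def f(xx, g, h, beta):
        return g * xx**beta - h * np.sqrt(xx)

    popt, _ = optimize.curve_fit(
        f, bx, by, p0=list(p0), sigma=bw, absolute_sigma=False,
        bounds=([1e-6, 1e-6, 0.51], [50, 50, 1.49]), maxfev=50000,
    )
    return GrowthLaw(g=float(popt[0]), h=float(popt[1]), beta=float(popt[2]))


def fit_success_rate(
    events: Sequence[tuple[float, bool]], v: float
) -> tuple[float, float]:
    """Maximum-likelihood catastrophe rate from (gap d, fused) outcomes.

    The success probability over a gap d is S(d) = e^(−αd/v); the Bernoulli
    log-likelihood is maximized for α ≥ 0, with the standard error from the
    observed Fisher information.  Returns (α̂, se).  All-fused data sit on the
    α = 0 boundary (se = nan with a degenerate information).
    """
    ev = [(float(d), bool(f)) for d, f in events]
    if len(ev) < 20:
        raise ValueError("need at least 20 events")
    d = np.array([x for x, _ in ev])
    fused = np.array([f for _, f in ev])
    if fused.all():
        return 0.0, float("nan")
    if not fused.any():
        raise ValueError("no fused events: alpha unbounded")

    t = d / v  # exposure times

    def nll(alpha):
        a = alpha[0]
        if a < 0:
            return 1e12
        s = np.exp(-a * t)
        s = np.clip(s, 1e-300, 1.0 - 1e-15)
        return -float(np.sum(np.where(fused, -a * t, np.log1p(-s))))

    res = optimize.minimize(nll, x0=[0.1], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    a_hat = max(float(res.x[0]), 0.0)
    # observed information by central differences
    eps = max(1e-6, 1e-4 * a_hat)
    info = (nll([a_hat + eps]) - 2 * nll([a_hat]) + nll([a_hat - eps])) / eps**2
    se = 1.0 / math.sqrt(info) if info > 0 else float("nan")
    return a_hat, se
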