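"""Closed-form and semi-analytic theory of the liquid network.

Two levels of description are implemented:

1. *Hexagonal mean field.*  Treating the network as hexagons of edge length λ,
   total length grows by spawning (rate k per unit length, each successful
   event spanning a cell, length ≈ √3·λ) and shrinks by junction sliding at
   average speed γ·b per junction.  The balance gives a steady-state mean area
   ⟨A⟩ = (3√3/2)·λ² = γ·b/k.  With a Poissonian tip catastrophe (rate α, tip
   speed v) the spawning term acquires the survival factor e^(−√3αλ/v) and the
   balance becomes transcendental; above a critical rate α_c no steady state
   exists and the density diverges.

2. *Polygon population model.*  Polygon areas drift deterministically by
   (τ/⟨A⟩)·dA/dt = g·(A/⟨A⟩)^β − h·(A/⟨A⟩)^{1/2} and are split at hazard
   k̂·√A (splitting is proportional to perimeter).  This yields closure times,
   survival times, and — via flux balance between polygon disappearance at
   zero area and creation by splitting — a matched steady-state area
   distribution P(A) with a power-law rise at small areas and a stretched
   exponential tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "GrowthLaw",
    "MeanFieldModel",
    "MeanFieldSolution",
    "hex_steady_state",
    "catastrophe_steady_state",
    "critical_catastrophe_rate",
    "drift",
    "closure_time",
    "survival_time",
    "steady_state_distribution",
    "atp_rate",
    "SPLIT_PREFACTOR",
]

#: Splitting-rate geometry factor: a spawn event on a polygon's perimeter
#: splits that polygon with probability 1/2 (each edge borders two faces), and
#: a hexagon of area A has perimeter sqrt(8*sqrt(3)*A), so
#: k_split = (k/2)*P = k*sqrt(2*sqrt(3)*A) — i.e. khat = sqrt(2*sqrt(3))*k*sqrt(A)/sqrt(A).
SPLIT_PREFACTOR = math.sqrt(2.0 * math.sqrt(3.0))


@dataclass(frozen=True)
class GrowthLaw:
    """Nondimensional polygon drift law (τ/⟨A⟩)·dA/dt = g·x^β − h·x^{1/2}."""

    g: float = 1.69
    h: float = 1.85
    beta: float = 0.78

    def __post_init__(self):
        if not (self.g > 0 and self.h > 0):
            raise ValueError("g and h must be > 0")

    @property
    def x_cutoff(self) -> float:
        """Normalized area above which polygons grow: (h/g)^(1/(β−1/2))."""
        try:
            return (self.h / self.g) ** (1.0 / (self.beta - 0.5))
        except OverflowError:
            return math.inf

    def rate(self, x):
        """Nondimensional drift of x = A/⟨A⟩ per unit t/τ."""
        x = np.asarray(x, float)
        return self.g * x**self.beta - self.h * np.sqrt(x)


@dataclass(frozen=True)
class MeanFieldModel:
    """Growth law plus splitting hazard and the dimensional scales."""

    law: GrowthLaw = field(default_factory=GrowthLaw)
    khat_nd: float = 0.8988   # nondimensional splitting prefactor (see solver)
    mean_area: float = 1.0    # ⟨A⟩, µm²
    tau: float = 1.0          # network timescale, s


@dataclass
class MeanFieldSolution:
    """Matched steady-state polygon-area distribution (nondimensional units)."""

    law: GrowthLaw
    z: float          # 3/2 − β
    c1: float         # normalization of the small-area branch c1·x^{−1/2}
    c2: float         # stretched-exponential scale, = k̂/(g·z)
    c3: float         # continuity constant at the matching point
    x_star: float     # matching area in units of ⟨A⟩
    khat_nd: float    # self-consistent nondimensional splitting prefactor
    j0: float         # flux of polygons vanishing at zero area (per τ)
    j_split: float    # polygon production flux by splitting (per τ)
    mean_bk: float    # predicted ⟨A⟩ in units of b/k
    a_star_bk: float  # matching area in units of b/k

    def pdf(self, x):
        """Steady-state probability density of x = A/⟨A⟩."""
        x = np.asarray(x, float)
        small = self.c1 * np.power(x, -0.5, where=x > 0,
                                   out=np.zeros_like(x))
        large = self.c1 * self.c3 * x**(-self.law.beta) * np.exp(
            -self.c2 * x**self.z)
        return np.where(x < self.x_star, small, large)

    def cdf(self, x):
        x = np.atleast_1d(np.asarray(x, float))
        return np.array([
            integrate.quad(self.pdf, 0, xi, limit=200)[0] for xi in x
        ])


# ---------------------------------------------------------------- hexagonal
def hex_steady_state(b: float, k: float, gamma: float = 0.29):
    """Steady-state edge length λ and mean polygon area of the hexagonal model.

    Returns (λ, ⟨A⟩) with ⟨A⟩ = γ·b/k and λ = sqrt(2γb/(3√3 k)).
    """
    if not (b > 0 and k > 0 and gamma > 0):
        raise ValueError("b, k, gamma must be > 0")
    mean_area = gamma * b / k
    lam = math.sqrt(2.0 * mean_area / (3.0 * math.sqrt(3.0)))
    return lam, mean_area


def catastrophe_steady_state(
    b: float, k: float, gamma: float = 0.29, v: float = 1.0, alpha: float = 0.0
):
    """Steady-state λ under tip catastrophe: λ²·e^(−√3αλ/v) = 2γb/(3√3 k).

    Returns (λ, diverged): the smallest positive root, or (nan, True) when the
    catastrophe rate exceeds the critical value and no steady state exists.
    λ(α=0) coincides with the pure hexagonal steady state.
    """
    lam0, _ = hex_steady_state(b, k, gamma)
    if alpha <= 0:
        return lam0, False
    C = 2.0 * gamma * b / (3.0 * math.sqrt(3.0) * k)
    s3 = math.sqrt(3.0)

    def f(lam):
        return lam * lam * math.exp(-s3 * alpha * lam / v) - C

    lam_peak = 2.0 * v / (s3 * alpha)  # maximum of the left-hand side
    if f(lam_peak) < 0:
        return float("nan"), True
    # smallest root lies between λ(α=0) and the peak
    lo = min(lam0, lam_peak)
    if f(lo) > 0:
        lo = 1e-12 * lam_peak
    root = optimize.brentq(f, lo, lam_peak, xtol=1e-14, rtol=1e-12)
    return float(root), False


def critical_catastrophe_rate(
    b: float, k: float, gamma: float = 0.29, v: float = 1.0
) -> float:
    """Critical catastrophe rate α_c = (1/e)·sqrt(2√3·k·v²/(γ·b)), s⁻¹.

    Above α_c the steady-state balance admits no finite edge length: dλ/dα
    diverges and the mean polygon area grows without bound.
    """
    if not all(x > 0 for x in (b, k, gamma, v)):
        raise ValueError("all parameters must be > 0")
    return math.sqrt(2.0 * math.sqrt(3.0) * k * v * v / (gamma * b)) / math.e


# ----------------------------------------------------------- polygon model
def drift(A, model: MeanFieldModel):
    """Dimensional drift dA/dt (µm²/s) of a polygon of area A."""
    x = np.asarray(A, float) / model.mean_area
    return model.mean_area / model.tau * model.law.rate(x)


def closure_time(A0: float, model: MeanFieldModel) -> float:
    """Time for a shrinking polygon to reach zero area; ∞ if it grows.

    t* = ∫_0^{x0} dx / (h√x − g·x^β) in units of τ; the integrand ~ x^{−1/2}
    at the origin, so the quadrature converges.  For g = 0 the closed form is
    t* = 2√x0/h.
    """
    law = model.law
    x0 = A0 / model.mean_area
    if x0 <= 0:
        return 0.0
    if x0 >= law.x_cutoff:
        return math.inf
    val, _ = integrate.quad(
        lambda x: 1.0 / (law.h * math.sqrt(x) - law.g * x**law.beta),
        0.0, x0, limit=200, points=[0.0],
    )
    return float(val) * model.tau


def survival_time(A0: float, model: MeanFieldModel, rtol: float = 1e-8) -> float:
    """Mean time before a polygon of initial area A0 closes or splits, s.

    The deterministic area trajectory is integrated together with the
    accumulated splitting hazard H(t) = k̂∫√x dt′ and the survival-weighted
    time ∫e^(−H)dt′, up to closure (shrinking polygons) or until survival is
    negligible (growing polygons, where the hazard diverges with the area).
    With k̂ = 0 this equals the closure time exactly.
    """
    law = model.law
    x0 = A0 / model.mean_area
    if x0 <= 0:
        return 0.0
    khat = model.khat_nd
    if khat == 0 and x0 >= law.x_cutoff:
        return math.inf

    def rhs(t, y):
        x = max(y[0], 0.0)
        sx = math.sqrt(x)
        return [law.g * x**law.beta - law.h * sx,
                khat * sx,
                math.exp(-y[1])]

    def closed(t, y):
        return y[0] - 1e-12

    closed.terminal = True
    closed.direction = -1

    def dead(t, y):
        return y[1] - 50.0

    dead.terminal = True
    dead.direction = 1

    t_end = 1e4 if x0 >= law.x_cutoff else 10.0 + 5.0 * closure_time(
        A0, model) / model.tau
    sol = integrate.solve_ivp(
        rhs, (0.0, t_end), [x0, 0.0, 0.0], events=[closed, dead],
        rtol=rtol, atol=1e-12, max_step=t_end / 50,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"survival-time quadrature failed: {sol.message}")
    return float(sol.y[2, -1]) * model.tau


def steady_state_distribution(
    law: Optional[GrowthLaw] = None,
    split_prefactor: float = SPLIT_PREFACTOR,
) -> MeanFieldSolution:
    """Solve the matched steady-state polygon-area distribution.

    The small-area branch P(x) = c1·x^{−1/2} is forced by a finite flux of
    vanishing polygons (drift ∝ √x near zero); the large-area branch
    c1·c3·x^{−β}·e^{−c2·x^z} (z = 3/2 − β, c2 = k̂/(g·z)) solves the
    stationary transport equation with splitting.  Continuity at the matching
    point x*, normalization, unit mean (self-consistency of ⟨A⟩), and the
    flux balance J0 = J_split determine (c1, x*, k̂).

    The conversion to units of b/k uses k̂ = √(2√3·⟨A⟩k/b)·(see
    SPLIT_PREFACTOR): solving k̂² = 2√3·γ for γ = ⟨A⟩k/(b) makes the
    predicted mean area and matching area dimensionful.
    """
    law = law if law is not None else GrowthLaw()
    z = 1.5 - law.beta
    if z <= 0:
        raise ValueError("growth exponent beta must be < 3/2")

    def branches(x_star, khat):
        c2 = khat / (law.g * z)
        c3 = x_star ** (law.beta - 0.5) * math.exp(c2 * x_star**z)

        def p_small(x):
            return x**-0.5

        def p_large(x):
            return c3 * x**(-law.beta) * math.exp(-c2 * x**z)

        return c2, c3, p_small, p_large

    def moments(x_star, khat):
        _, _, ps, pl = branches(x_star, khat)
        kw = dict(limit=200)
        i0 = integrate.quad(ps, 0, x_star, **kw)[0] + \
            integrate.quad(pl, x_star, np.inf, **kw)[0]
        i1 = integrate.quad(lambda x: x * ps(x), 0, x_star, **kw)[0] + \
            integrate.quad(lambda x: x * pl(x), x_star, np.inf, **kw)[0]
        ih = integrate.quad(lambda x: math.sqrt(x) * ps(x), 0, x_star, **kw)[0] \
            + integrate.quad(lambda x: math.sqrt(x) * pl(x), x_star, np.inf,
                             **kw)[0]
        return i0, i1, ih

    def equations(q):
        x_star, khat = q
        if x_star <= 0 or khat <= 0:
            return [1e6, 1e6]
        i0, i1, ih = moments(x_star, khat)
        c1 = 1.0 / i0
        return [c1 * i1 - 1.0,          # unit nondimensional mean
                law.h - khat * ih]      # J0 = J_split (both per c1)

    sol = optimize.root(equations, x0=[0.5, 0.9], tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"mean-field matching failed: {sol.message} "
                           f"(residuals {sol.fun})")
    x_star, khat = (float(v) for v in sol.x)
    i0, i1, ih = moments(x_star, khat)
    c1 = 1.0 / i0
    c2, c3, _, _ = branches(x_star, khat)
    gamma = khat**2 / split_prefactor**2
    return MeanFieldSolution(
        law=law, z=z, c1=c1, c2=c2, c3=c3, x_star=x_star, khat_nd=khat,
        j0=law.h * c1, j_split=khat * c1 * ih,
        mean_bk=gamma, a_star_bk=x_star * gamma,
    )


# ------------------------------------------------------------------ energy
def atp_rate(
    L: float, k: float, b: float, ds: float = 0.008, gamma: float = 0.29
) -> float:
    """Order-of-magnitude ATP consumption of network maintenance, ATP/s.

    Tubule spawning by motor-driven extension costs one ATP per motor step of
    size ds.  Spawns occur at rate k·L and each traverses on average the
    inscribed hexagon diameter √3·λ = sqrt(2γ/√3)·ℓ with ℓ = sqrt(b/k), so the
    estimate is sqrt(2γ/√3)·L·k·ℓ/ds.  This counts only successful extension
    against tension, not basal motor activity.
    """
    if not all(x > 0 for x in (L, k, b, ds)):
        raise ValueError("L, k, b, ds must be > 0")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    ell = math.sqrt(b / k)
    return math.sqrt(2.0 * gamma / math.sqrt(3.0)) * L * k * ell / ds
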