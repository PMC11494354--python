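"""Simulation parameters and domain geometry.

The liquid-network model is governed by two physical parameters — the junction
mobility ``b`` (µm/s) and the tubule spawning rate ``k`` (µm⁻¹s⁻¹) — from which the
emergent length scale ``ℓ = sqrt(b/k)`` and timescale ``τ = 1/sqrt(b·k)`` follow by
dimensional analysis.  All remaining parameters (diffusivity, tip speed, catastrophe
rate, pinning rates, event thresholds) are secondary: the steady state is insensitive
to the numerical thresholds over a wide range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = ["DomainBoundary", "SimParams"]


@dataclass(frozen=True)
class DomainBoundary:
    """Spatial domain enclosing the network.

    kind
        ``"circle"`` (immobile rim at ``radius``), ``"periodic"`` (rectangle with
        periodic wrapping, side lengths ``extents``), or ``"none"`` (unbounded;
        only stable with sufficient catastrophe).
    """

    kind: str = "circle"
    radius: float = 15.0  # µm, circle
    extents: tuple[float, float] = (30.0, 30.0)  # µm, periodic rectangle

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "periodic", "none"):
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if self.kind == "circle" and not self.radius > 0:
            raise ValueError("circle radius must be > 0")
        if self.kind == "periodic" and not all(e > 0 for e in self.extents):
            raise ValueError("periodic extents must be > 0")

    @property
    def area(self) -> float:
        if self.kind == "circle":
            return math.pi * self.radius**2
        if self.kind == "periodic":
            return self.extents[0] * self.extents[1]
        return math.inf


@dataclass(frozen=True)
class SimParams:
    """All physical and numerical parameters of one simulation.

    Units are µm and s throughout.  ``dt``, ``d_t1`` and ``d_close`` default to
    fractions of the emergent scales (``d_t1 = d_close = 0.05·ℓ``,
    ``b·dt = 0.1·d_t1``); steady-state structure is insensitive to these thresholds
    over at least a four-fold range.
    """

    b: float = 0.02       # junction mobility, µm/s
    k: float = 0.005      # tubule spawning rate, µm⁻¹ s⁻¹
    D: float = 1e-5       # junction diffusivity, µm²/s
    v: float = 1.0        # tip growth speed, µm/s
    alpha: float = 0.0    # catastrophe rate, s⁻¹ (0 = off)
    k_p: float = 0.0      # global pinning rate, s⁻¹
    k_u: float = 0.0      # per-pin unpinning rate, s⁻¹
    dt: Optional[float] = None      # timestep, s (None → auto)
    d_t1: Optional[float] = None    # T1 contact threshold, µm (None → 0.05·ℓ)
    d_close: Optional[float] = None  # loop-closure merge threshold, µm
    growth_mode: str = "instant"    # "instant" | "finite"
    domain: DomainBoundary = field(default_factory=DomainBoundary)
    seed: int = 0

    # -- derived scales ---------------------------------------------------
    @property
    def ell(self) -> float:
        """Emergent length scale ℓ = sqrt(b/k), µm."""
        return math.sqrt(self.b / self.k)

    @property
    def tau(self) -> float:
        """Emergent timescale τ = 1/sqrt(b·k), s."""
        return 1.0 / math.sqrt(self.b * self.k)

    def resolved(self) -> "SimParams":
        """Return a copy with all auto thresholds filled in and validated."""
        d_t1 = self.d_t1 if self.d_t1 is not None else 0.05 * self.ell
        d_close = self.d_close if self.d_close is not None else d_t1
        dt = self.dt if self.dt is not None else 0.1 * d_t1 / self.b
        p = replace(self, d_t1=d_t1, d_close=d_close, dt=dt)
        p.validate()
        return p

    def validate(self) -> None:
        if not (self.b > 0 and self.k > 0 and self.v > 0):
            raise ValueError("b, k, v must be > 0")
        if min(self.D, self.alpha, self.k_p, self.k_u) < 0:
            raise ValueError("D, alpha, k_p, k_u must be >= 0")
        if self.growth_mode not in ("instant", "finite"):
            raise ValueError(f"unknown growth_mode {self.growth_mode!r}")
        if self.dt is not None:
            if not self.dt > 0:
                raise ValueError("dt must be > 0")
            if self.d_t1 is not None and self.b * self.dt > 0.5 * self.d_t1:
                raise ValueError(
                    "stability guard violated: b*dt must be <= 0.5*d_t1 "
                    f"(b*dt={self.b * self.dt:g}, d_t1={self.d_t1:g})"
                )
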