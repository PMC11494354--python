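# Methods

## The model

The peripheral endoplasmic reticulum of adherent cells is a planar network of
membrane tubules meeting at three-way junctions.  `liquidnet` models it as an
*active liquid network*: a spatial graph whose straight edges carry a
constant, length-independent tension, and whose topology changes through
stochastic tubule growth and tension-driven rearrangements.

Each junction obeys the overdamped Langevin equation

    dr_i/dt = −b ∇f(r_i) + sqrt(2D) η(t),      f(r_i) = Σ_j |r_i − r_j|,

so the deterministic velocity is the mobility `b` times the sum of unit
vectors toward the junction's neighbors: every tubule pulls with the same
tension regardless of its length.  `D` is a small junction diffusivity
(default 1e-5 µm²/s); the shape statistics of the steady state are driven by
the tension dynamics, not by this noise.

Topology evolves by four elementary processes:

* **T1 neighbor swaps.**  When two connected degree-3 junctions approach
  within the contact threshold `d_T1`, the two alternative pairings of their
  four external neighbors are evaluated at fixed coordinates, and the
  reconnection is applied only if it strictly reduces the total local edge
  length (and introduces no local edge crossing).
* **Loop closure.**  A T1 can leave two junctions doubly connected — a 2-gon
  loop, which contracts because twice as much tension pulls the pair together
  as apart.  When the pair separation falls below `d_close` the pair is merged
  and the remnant degree-2 junction is spliced into a single straight tubule,
  annihilating the enclosed face.
* **Tubule spawning.**  New tubules nucleate on the existing network as a
  Poisson process with rate `k` per unit length, uniformly along the length.
  A new tubule grows *perpendicular to its mother tubule* (random side) —
  see "Design choices" — and, in the default instantaneous mode (justified by
  tip speeds v ≫ b), immediately spans the enclosing polygon: the ray from the
  spawn point either fuses with the first edge it meets, splitting one face
  into two, or retracts leaving the network exactly as before.
* **Catastrophe.**  A growing tip survives a gap of width d with probability
  exp(−α·d/v).  In the finite-speed mode the tip instead advances v·dt per
  step, suffers catastrophe with per-step probability 1 − exp(−α·dt), and
  fuses on contact; the two modes give statistically consistent steady states
  and the finite mode exists to validate the instantaneous approximation.

Reversible **pinning** immobilizes junctions (tethering to cytoskeleton or
organelles): a global Poisson process of rate `k_p` pins a random free
junction and each pin releases at rate `k_u`, so `n_p = k_p/k_u` pins exist at
stationarity.  The global-rate convention (rather than per-junction pinning)
keeps `k_p` in s⁻¹ and makes a rate pair such as (10 s⁻¹, 0.01 s⁻¹) maintain
about a thousand pins.

Dimensional analysis leaves one emergent length ℓ = sqrt(b/k) and one
timescale τ = 1/sqrt(b·k).  Balancing tubule creation against tension-driven
removal for a hexagonal network of edge length λ,

    dL/dt = k·L·λ·√3 − γ·b·n,

gives the steady-state mean polygon area ⟨A⟩ = (3√3/2)·λ² = γ·b/k, with γ the
dimensionless sliding coefficient.  The simulations in this package yield
per-run coefficients γ ≈ 0.25–0.35 across a 30-fold range of b/k, with a
zero-intercept sweep slope of ≈ 0.27 (mildly decreasing toward sparse
networks, a finite-domain effect of the immobile enclosure).

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| b | junction mobility | µm/s | 0.02 |
| k | tubule spawning rate per length | µm⁻¹s⁻¹ | 0.005 |
| D | junction diffusivity | µm²/s | 1e-5 |
| v | tip growth speed | µm/s | 1.0 |
| alpha | catastrophe rate | s⁻¹ | 0 (off) |
| k_p, k_u | pinning / unpinning rates | s⁻¹ | 0 (off) |
| d_T1 | T1 contact threshold | µm | 0.05·ℓ |
| d_close | loop-closure merge threshold | µm | d_T1 |
| dt | timestep | s | 0.1·d_T1/b |
| domain | circle (radius 15 µm), periodic rectangle, or none | — | circle |

The defaults (b = 0.02 µm/s, k = 0.005 µm⁻¹s⁻¹) correspond to the
physiological regime: with the measured COS7 spawning rate
8.5×10⁻³ µm⁻¹s⁻¹ and mean polygon area ≈ 1 µm², the inferred junction
mobility is b = ⟨A⟩k/γ ≈ 0.03 µm/s.

Threshold insensitivity: the steady-state density coefficient varies by less
than ~15% when `d_T1` and `d_close` change together over an eight-fold range
(0.025ℓ–0.2ℓ), and is unchanged under a four-fold smaller timestep.

## Numerical choices

* **Integration** is explicit Euler–Maruyama with fixed dt subject to the
  stability guard b·dt ≤ 0.5·d_T1 (default 0.1·d_T1), so per-step displacement
  is small against every event threshold.  Event order within a step is fixed
  (motion → T1 → closures → growth → pinning); order effects vanish with dt.
* **Edge crossings.**  Topological events carry local planarity guards (a
  candidate T1 or closure whose new geometry would properly cross a nearby
  edge is skipped or deferred), so events preserve the embedding exactly.
  Junction *motion*, however, is unconstrained by default: transient
  pass-throughs of flattened faces are permitted and resolve under tension.
  This is deliberate — enforcing strict planarity at every step (available as
  `planarity="strict"`, implemented as move rejection with tangential sliding
  along the obstruction) jams flattened faces against their neighbors and
  measurably densifies the steady state (coefficient ~0.55 b/k instead of
  ~0.31 b/k) while distorting the morphology.  Polygon analysis excludes
  inverted (negative-area) faces arising from transient tangles; on periodic
  domains these are absent at steady state, and on the circular domain they
  are confined to the immobile rim.
* **Rim handling.**  The clipped circular domain keeps every hexagon whose
  center lies inside the circle; the union's perimeter nodes are flagged
  immobile.  Faces bounded partly by rim-rim edges are excluded from polygon
  statistics (`drop_rim`), since the immobile enclosure distorts them.
* **Degenerate events.**  2-gon edges are geometrically coincident, so they
  are neither spawn substrates nor fusion targets (a ray whose first hit is a
  2-gon edge retracts); splices that would create a triple edge force-close
  the existing 2-gon first; retraction restores the pre-spawn topology
  exactly, including for spawns based on rim edges.
* **Quadratures and roots** in the mean-field module use adaptive quadrature
  (abs. tol. 1e-10 or better) and bracketed Brent root finding; the matched
  distribution is solved by a two-variable Newton iteration on (A*, k̂) with
  normalization eliminated analytically.

## Design choices made where the model description is open

* **Spawn direction: perpendicular to the mother tubule.**  The mean-field
  growth term k·L·λ·√3 models each successful spawn as crossing the full
  distance between parallel edges of its cell, i.e. a transverse crossing.
  Isotropic oblique spawn directions instead cut off mostly short-lived
  sliver triangles (more than a third of splits), which halves the effective
  face production and doubles the steady-state mean-area coefficient.
  Perpendicular nucleation realizes the model the growth term describes; an
  optional jitter cone around the normal supports sensitivity tests.
* **T1 acceptance by strict local length decrease** at fixed coordinates, the
  simplest rule consistent with tension relaxation ("length-minimizing"
  rearrangements).  Variants with repositioning or separating-pull scoring
  were explored and rejected: they accelerate face annihilation and raise the
  density coefficient away from the observed value.
* **Boundary junctions of the circular enclosure are permanently immobile.**
  Under pure tension a free-boundary network collapses; the immobile rim
  mimics the enclosure used for the reference simulations.  (The alternative
  — junctions mobile along the circle — is not implemented.)
* **Tip–tip fusion is disallowed**; growing tips fuse only into existing
  tubules.  Tips are rare at any instant (of order k·L·⟨gap⟩/v ≈ a few), so
  this choice is immaterial at v ≫ b.
* **⟨A⟩ is the unweighted mean over faces**, not area-weighted.

## Mean-field polygon-population model

Polygons are treated as an aspatial population with deterministic drift

    (τ/⟨A⟩)·dA/dt = g·(A/⟨A⟩)^β − h·(A/⟨A⟩)^{1/2}

(growth of large polygons, shrinkage of small ones; reference fitted values
g = 1.69, h = 1.85, β = 0.78, zero crossing at A ≈ 1.38·⟨A⟩) and a splitting
hazard k̂·√A proportional to perimeter.  From these follow closure times
(t* = ∫ dA/|v(A)|), survival times (hazard accumulated along the
deterministic trajectory — longest near the drift cutoff, since intermediate
polygons both shrink slowly and split rarely), and the steady-state area
distribution: a c₁·A^(−1/2) small-area branch forced by a finite closure
flux, matched at A* to a c₁c₃·A^(−β)·exp(−c₂A^z) branch (z = 3/2 − β,
c₂ = k̂/(g·z)) solving the stationary transport equation with splitting.
Continuity, normalization, unit mean, and the flux balance
J₀ = J_split = ∫k̂√A·P dA determine (c₁, A*, k̂).

The dimensional mapping of the splitting prefactor follows from geometry: a
spawn event on a polygon's perimeter splits it with probability 1/2 (each
tubule borders two faces) and a hexagon of area A has perimeter
sqrt(8√3·A), so k̂ = sqrt(2√3)·k·… in units where ⟨A⟩ = τ = 1 this gives
k̂ = sqrt(2√3·γ) with γ = ⟨A⟩k/b.  Solving the matched system with the
reference growth law then *predicts* γ ≈ 0.233 (mean area 0.23·b/k) and
A* ≈ 0.118·b/k, with no parameter fitted to the simulated density.  The
model neglects stochasticity of individual polygon trajectories, so its
survival times are slight overestimates, and its daughter-size injection is
ignored at small areas.

With catastrophe the growth term acquires the survival factor
exp(−√3αλ/v); the steady-state balance λ²·exp(−√3αλ/v) = 2γb/(3√3k) loses
its root at α_c = (1/e)·sqrt(2√3·k·v²/(γb)) — beyond this rate the network
cannot sustain a finite density.

## What the synthetic data emulate — and what they do not

The simulator itself generates all test inputs; there is no external data.
Synthetic fixtures (perturbed lattices, polygon-track ensembles integrated
from a prescribed growth law, Bernoulli catastrophe outcome sets) provide
known ground truth for every fitting operation.  Real ER image analysis
involves segmentation error, a localization-error jump in the EMMD, finite
optical resolution censoring small polygons, and heterogeneous spawning —
none of which are modeled here.  Passing tests therefore demonstrate the
internal consistency of the model and pipeline, not segmentation robustness.

## Problem sizes

Desk-scale defaults: a 15 µm-radius circular domain (a few hundred to two
thousand polygons depending on b/k), equilibrated for five network timescales
from a sparse honeycomb (3× the steady-state edge length), with polygon
frames recorded every 0.05·τ for 2.5–4·τ where tracking is needed.  A full
eight-point parameter sweep with all analyses completes in a few minutes on
one CPU.  These sizes are the package's chosen trade-off between sampling
error (a few percent on the density coefficient) and runtime.

## Known limitations

* Strict per-step planarity and physiological density cannot currently be had
  together; the default permits transient pass-throughs (see above).
* The finite-speed growth mode advances tips in discrete v·dt jumps and
  disallows tip–tip interactions.
* The periodic domain requires a commensurate honeycomb, so the initial
  lattice is slightly anisotropic (edge lengths adjusted per axis).
* Survival-time estimates from tracking are right-censored by the recording
  window; the comparison with theory accounts for the resulting downward
  bias qualitatively (theory ≥ simulation), not quantitatively.
* The 3D extension (tubules fusing within a contact radius, an extra length
  scale) is out of scope; only the planar model is implemented.
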