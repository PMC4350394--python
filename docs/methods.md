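# Methods

This note records the model, the numerical choices, and what the synthetic
fixtures do and do not establish.

## Reaction–diffusion model

The activator–inhibitor system

    ∂u/∂t = u − u³/3 − v + D Δ_LB u
    ∂v/∂t = ε (u + β + k S),    S = ∫ H(u) dA

is the generic excitable-media description of spreading depression (SD):
*u* carries the front, *v* the slow recovery, and the global feedback term
k·S (excited surface area times coupling) raises the effective threshold as
the wave grows, confining it to a localized segment. The Heaviside
threshold is u > 0 (strict inequality; the set u = 0 has measure zero along
trajectories) and is exposed as a parameter.

Parameter presets: `bump-study` (ε = 0.04, β = 0.9, k = 0.003, D = 1) and
`v1-study` (ε = 0.04, β = 1.2, k = 0.0045, D = 1). Units are dimensionless
model units; when a mesh represents cortex an `mm_per_unit` scale may be
attached as metadata but enters no computation.

Two dynamical facts shape everything downstream:

* **For β < 1 the uniform state is an unstable focus.** The inhibitor has
  no self-decay, so the local Jacobian has trace 1 − β². At β = 0.9 any
  region left to itself oscillates up to a collective firing on a time
  scale of ~25 time units. Quiescent tissue is only stable while a segment
  exists, because the feedback shifts the background to
  u = −(β + kS) < −1.
* **The propagation boundary.** 1D pulse propagation fails above a critical
  threshold; bisection on the 1D benchmark locates it at β_c ≈ 1.393
  (ε = 0.04, D = 1, k = 0). The feedback holds a stable segment at an
  effective threshold just below β_c; at k = 0.003, β = 0.9 this selects an
  excited area S* ≈ 140.

## Discretisation

* **Operator.** Cotangent finite-element stiffness with barycentric lumped
  mass (one third of incident triangle areas). Row sums are cancelled to
  zero after assembly, so constants are annihilated to machine precision;
  on the structured sheets (uniform diagonal split, six triangles per
  interior vertex) the operator reduces exactly to the five-point
  Laplacian, and Δ(x² + y²) = 4 holds to round-off at interior vertices.
  No-flux boundaries are natural; periodic boundaries are vertex
  identifications folded into the matrix, so the solver sees a closed
  torus-topology operator.
* **Time stepping.** IMEX trapezoidal: Crank–Nicolson for D·Δ_LB u with a
  prefactorised sparse LU, explicit Heun predictor–corrector for the
  reaction terms; v has no diffusion. Measured temporal order ≈ 1.93 on a
  smooth 1D benchmark. S is recomputed once per step from the pre-step
  state (the feedback term is therefore first-order in time; it is a slow
  ε-scale forcing). Defaults dt = 0.05 (guarded: the explicit reaction part
  requires dt ≤ 0.25), linear-solve tolerance 10⁻⁹ (direct LU in
  practice), target edge length 1.0 for the experiment sheets.
* **1D benchmark.** A dedicated periodic 1D solver with the same scheme
  provides the planar-pulse references: speed 1.3029 at the default grid
  (resolution 0.25, dt 0.05), 1.3037 on a 4× finer oracle grid — the
  frozen regression constant; √D speed scaling holds to 0.1%. The speed
  window ends at t = 40, before the β < 1 background instability fires the
  wake.

## Wave-segment protocol

The published recipe — excite a strip, inhibit the region left of it
(v = 0.5), let a planar pulse form with k = 0, cut its open ends to the
equilibrium state, then switch k on and damp transients — fails literally
at desk-scale resolution, for two reasons established experimentally (see
the area-trajectory scans in the test suite's provenance): the inhibited
region fires collectively at t ≈ 25 (background instability above), and
switching k on over a large excited band makes v integrate the excess area
and extinguish the wave (every cut height between 2 and 14 dies within
t ≈ 15–25).

The implemented protocol keeps the published stages and amends the cut:

1. strip (u = 1) + left inhibition (v = 0.5), 400 steps with k = 0
   (stopping before the background fires);
2. **cut**: keep a small seed box at the pulse's leading edge
   (depth 4 + 3 ahead, half-height 6), lay a trailing v = 0.5 guard band
   (width 8) so the seed cannot ignite backwards, and put everything else
   at the feedback-consistent background u = −β_eff with β_eff = 1.35,
   the effective threshold just below the propagation boundary at which
   the feedback will hold the segment;
3. k on, 2400 steps. The seed grows into the segment attractor from below
   (S: ~65 → ~140), which is robust, where shrinking from above is not.

The delivered segment is a thin arc (≈ 6 units deep × 22 wide) travelling
at ≈ 0.6 units/time. Stationarity is enforced as a secular drift of the
excited area < 1% per 100 steps, fitted over a 2000-step window: at the
default resolution the segment carries a grid-induced *breathing*
oscillation (±25% in area at edge length 1.0, ±5% at 0.5, period ≈ 50 time
units) that averages out over the window. The breathing shrinks under
refinement, so we treat it as a discretisation artifact around the
stationary solution; consequences: the "unperturbed segment has flat area"
idealisation holds only to the breathing amplitude at desk scale, and
breathing classifications compare against this baseline.

`v1-study` parameters select a much smaller segment (S* ≈ 33, about 4 × 8
length units). No protocol variant we tried (seeds down to S₀ ≈ 11,
β_eff ∈ [1.26, 1.37], edge length down to 0.5) sustains it; the attractor
appears to need finer resolution than desk scale affords. Stable-segment
experiments therefore run at the bump-study parameters.

## Scattering experiments

The staged segment is translated on its periodic staging sheet (whole-cell
rolls), isolated (fields flattened to the far-field background outside a
box around the COG, trimming the slowly decaying inhibitor wake), and
copied index-wise onto a bump sheet built on the same planar grid — for a
height-graph bump this is nearest-point projection along the normal. The
run ends when the segment's centre of gravity (lumped-mass-weighted
centroid of {u > 0}, planar projection) has passed the bump support plus
one support radius and then travelled a further 12 units of arc — an
arc-length criterion, because strong deflections keep curving away from
the propagation axis — or when the activator stays below threshold for 5
consecutive snapshots (eradication).

The deflection angle ϕ is the angle between the incoming +x direction and
the least-squares direction of the post-bump tail, positive toward the
bump. At the published bump (amplitude 20, support 20) and bump-study
parameters the desk-scale sign structure is: eradication for head-on
offsets (d = 0), strong positive deflection at mid offsets (ϕ ≈ +70° at
d = 10 — the small segment is steered hard by the tall bump), and small
negative deflection in the tip-grazing regime (ϕ ≈ −0.5° at d = 28, the
empirically located fixture offset; the segment half-width is ≈ 11, so
only the tip samples the bump's negative-curvature rim there). A
zero-amplitude bump gives |ϕ| < 10⁻¹⁰ degrees. Mirror runs (launching on
the other side of the bump) flip the lab-frame angle; magnitudes agree to
≈ 10%, the mirror-asymmetry of the uniform-diagonal triangulation of the
bump, and the acceptance tolerance is set at 15% of |ϕ| (or 1°, whichever
is larger), fixed before measurement.

Head-on collisions at low bump amplitude (2–8) leave the segment alive
with damped breathing; at amplitude 20 the breathing grows (area peaks at
≈ 2.3× its stationary value) and the wave dies — the growth-then-
eradication signature of leaving the stable focus's basin.

Labyrinth maps run one scatter-style simulation per heading: the staged
segment is rotated by resampling its fields on the staging grid
(bilinear), stamped at the seed point, and run to a horizon; headings are
"permitted" if the segment still propagates there, "dead_end" if it was
eradicated. On a flat sheet all headings are permitted and the centre-of-
gravity paths are straight to round-off.

## Curvature estimation

Vertex normals are unweighted means of incident-face unit normals. The
osculating paraboloid z = ax² + bxy + cy² is fitted by least squares to the
ring neighbourhood in the local frame (vertex at origin, normal = +z);
ring 1 is the nearest neighbours, ring 2 the next-to-nearest only (graph
distance exactly 2). Coefficients are frame-dependent (the tangent basis
is an arbitrary rotation); H = a + c and K = 4ac − b² are the invariants.
κ₁,₂ = H ± √(H²−K) with the discriminant clipped at 0 (round-off on
umbilics). Degenerate fits (rank < 3, e.g. boundary or collinear rings)
return zero curvature with a flag and a warning, never an abort.

Robustification follows the two-ring comparison: δH = H − H̃ and
δK = K − K̃ across all vertices, Chauvenet's criterion
n·erfc(|δ − μ|/σ) < ½ exactly as printed (no 1/√2; sample mean and
standard deviation over the full list, candidate included; σ = 0 flags
nothing), and at flagged vertices the estimate of smaller *absolute* value
is kept — the conservative reading of "whichever value is smaller", since
the point of the procedure is to suppress artifact-inflated magnitudes;
the signed reading would prefer large negative artifacts (a `selection`
switch preserves it for comparison).

Hot spots are local minima of K below a (negative) threshold, thinned
greedily to a minimum geodesic separation, sorted most-negative-first —
the candidate SD nucleation points. Accuracy at the default fixtures:
sphere median K within 1% of 1/R², Gauss–Bonnet integrals within 0.3%
(sphere) and |∫K dA| < 0.3 (torus), torus hot spots on the inner equator
with K within 1.5% of the analytic value.

## Geodesics and paths

Discrete geodesics: Dijkstra on the edge graph for the homotopy class,
then curve-shortening — implicit (backward-Euler) smoothing of the
polyline alternated with reprojection onto the mesh (nearest point via a
face-centroid KD-tree and exact point-triangle distances), with periodic
resampling. Accuracy: flat sheet 2·10⁻⁵ relative, sphere great-circles
< 0.1% at the default refinement (the 2% acceptance bound is generous).
Endpoints are ordered canonically, so length(p, q) = length(q, p) exactly.
Exact polyhedral geodesics (MMP/funnel) are out of scope.

Path deviation is the per-direction mean (averaged over both directions)
and max of point-to-polyline distances, exactly symmetric under argument
swap. Aura arithmetic is the clinical bound: path length =
n_symptoms × minutes × speed (3 symptoms × 60 min × 3 mm/min = 540 mm),
coverage = 100·width·length/area (0.5 cm × 54 cm / 2000 cm² = 1.35%).

## Synthetic surfaces

Flat/bump sheets are structured grids (uniform diagonal split; periodic
seams by vertex identification with the bump support required strictly
inside, so identified vertices agree). The bump is
h(r) = A cos²(πr/2R), defaults A = R = 20. The ondulated sheet superposes
n randomly placed bumps of either sign (defaults: 12 bumps, amplitudes
2–6, supports 5–12 on a 100×100 sheet — gentle gyral-scale undulation with
both curvature signs) and is a pure function of its seed. Canonical
fixtures: icosphere, parametric torus, saddle patch.

What the fixtures do not establish: real cortical meshes are uneven at
voxel scale, non-structured, and carry areal/laminar heterogeneity; the
robustification path is exercised by synthetic displaced-vertex artifacts
only, and no claim is made to reproduce published patient-specific
curvature extrema or aura paths (non-public data).

## Known limitations

* The cut stage of the segment protocol is a desk-scale amendment of the
  published recipe (seed + guard band + shifted background); the published
  transient counts (≈800/≈1000 steps) are protocol parameters, not
  reproductions, since the original time step and mesh resolution are
  unstated.
* Grid-induced breathing (above) limits "stationary area" claims to the
  few-percent level at practical resolutions.
* v1-study segments are not sustainable at desk scale.
* The thin-slab thickness of the original bump domain is modelled as its
  2D mid-surface.
* Deflection-angle magnitudes are resolution- and segment-size-dependent;
  only the sign structure over offset is treated as established.
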