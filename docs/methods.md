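# Methods

## Model

A diffusion tensor image assigns to every voxel a symmetric
positive-definite tensor D. The package treats the volume as a
Riemannian manifold with metric G = D⁻¹: directions of strong diffusion
have low metric cost, so locally shortest paths (geodesics) gravitate
toward fiber orientations. A fiber is traced by integrating the geodesic
equation

    ẍ^γ = − Σ_{α,β} Γ^γ_αβ ẋ^α ẋ^β,
    Γ^γ_αβ = ½ Σ_σ g^{γσ} (∂_α g_βσ + ∂_β g_ασ − ∂_σ g_αβ),

with g_ij the components of G and g^{γσ} those of D. Because all tensors
involved are symmetric, only the 18 symbols with α ≤ β are computed and
stored; the quadratic form in the velocity doubles the off-diagonal
contributions instead of materializing all 27 entries.

Compared to eigenvector streamlining, the geodesic model uses the full
tensor (not just the principal eigenvector), admits multiple distinct
paths between two regions, and degrades more gracefully where anisotropy
is low. It assumes the tensor field is smooth enough for its inverse and
the inverse's derivatives to be meaningful; it does not model crossing
fibers within a voxel (a single tensor cannot represent them).

## Data preparation

Tracking needs four tensors at every evaluation point: D itself and the
three spatial derivatives of G. These are precomputed once per volume:

1. voxel-wise inversion of D (closed-form adjugate). If |det D| falls
   below `det_tol` (default 10⁻¹² × (mean trace / 3)³), the tensor is
   regularized by adding ε·I with ε = 10⁻⁶ × trace/3 (ε = 10⁻⁶ if the
   trace vanishes) and the voxel is flagged invalid in the validity
   mask;
2. component-wise central differences of G along each axis at interior
   voxels, first-order one-sided differences at boundary voxels,
   denominators taken from the per-axis voxel spacing (default 1).

At tracking time the four fields are interpolated component-wise
(trilinear over the 8 surrounding voxels, or nearest-neighbor). This is
deliberately *not* the same as interpolating D, inverting at the point
and differencing: interpolating the precomputed fields is cheaper, and
it is the variant whose behavior the tests characterize. Interpolation
ignores the validity mask by default (an optional strict mode errors
when any corner voxel is invalid).

Coordinates are 0-based continuous voxel coordinates with voxel centers
at integers; the tracking domain is the closed box [0, n−1] per axis,
outside which the 8-voxel neighborhood is undefined. For non-unit voxel
spacing the steppers convert velocities to physical units before
applying the quadratic form and convert the acceleration back, so the
geodesic is computed in physical space while positions remain in voxel
coordinates.

## Integration

Two fixed-step solvers are provided: explicit Euler

    x_{i+1} = x_i + h ẋ_i,   ẋ_{i+1} = ẋ_i − h Σ Γ^γ_αβ ẋ^α ẋ^β,

and the midpoint second-order Runge–Kutta scheme (half an Euler step,
then a full step with midpoint derivatives), the default. The midpoint
variant was fixed over Heun's; both are second order and the choice is
otherwise immaterial. Measured global convergence orders on the
half-plane oracle are 1.00 (Euler) and 2.00 (RK2).

The step size h is in voxel-traversal units: h = 0.05 means roughly
twenty steps per cell. Default h = 0.1; typical useful values lie in
0.1–0.2, with smaller h for oracle comparisons. The initial velocity is
normalized to Euclidean unit length (a metric-unit-speed option exists
for experiments); velocity is *not* renormalized during integration —
the continuous system conserves the metric speed ẋᵀGẋ exactly, so the
numerical drift of that quantity is a diagnostic of integrator error
(measured < 10⁻³ % over 1000 RK2 steps at h = 0.05 on the half-plane)
and correcting it would mask the signal.

Stopping conditions are exactly two: the fiber (or, for RK2, its
midpoint evaluation) leaving the volume, and a hard step cap
(`max_steps`, default 4096). Fibers are stored in full, one point per
completed step plus the seed.

The batch tracer advances all unfinished fibers together under an
active mask. Every operation is element-wise per fiber, so results are
bitwise identical across batch sizes and to single-fiber tracing — the
portable analogue of one-fiber-per-thread parallel execution, and a
property the test suite asserts exactly.

## Seeding

Seeds are positions in a box (uniform) or an explicit list, each paired
with one or more initial directions: uniform on the sphere, uniform in
a spherical cap about the local principal eigenvector, or fixed. Each
seed draws from a counter-derived RNG substream of the master seed, so
the draw for seed *i* is independent of how many seeds precede it.

## Streamline baseline

`trace_streamline` integrates the principal-eigenvector field of the
interpolated D with the same steppers and stopping rules, flipping the
eigenvector sign to keep a non-negative dot product with the previous
direction (the supplied reference at the first step). Where the top two
eigenvalues are degenerate (λ₁ − λ₂ < 10⁻⁹ λ₁) the eigenvector is
undefined: with a reference direction the reference is projected onto
the dominant eigenspace; without one, the tracker raises. This keeps
the baseline usable on planar-degenerate fields such as the half-plane
phantom, where it provably diverges from the geodesic tracker (the two
solve different ODEs).

## Connectivity post-processing

Filtering keeps fibers with at least one stored point inside the target
region (closed box bounds, or nearest-voxel membership for masks);
segments crossing a region between stored points do not count, which at
h ≤ 0.2 under-counts only regions thinner than a fifth of a voxel.
Ranking sorts by a user-supplied score, stably, with non-finite scores
flagged and placed last. The shipped default score — Euclidean length
over Riemannian length — equals 1 under an identity metric and grows
when a fiber follows high-diffusion corridors. It is a placeholder for
a proper connectivity measure, which is application-specific and
intentionally pluggable.

## Phantoms

All validation data is generated, noise-free by default:

- **homogeneous** — one tensor everywhere; derivative fields vanish
  identically, so geodesics must be exact straight lines.
- **half-plane** — D = diag(y², y², 1) with y = j·spacing + y0, i.e.
  the hyperbolic half-plane metric diag(y⁻², y⁻², 1) in each z-slice.
  Its geodesics are semicircles centered on y = 0 with the closed form
  x = c + r·tanh(τ/r), y = r·sech(τ/r); an `AnalyticFieldProvider`
  evaluates the exact tensors so integrator error can be isolated from
  field-discretization error. Default y0 = 4 keeps the metric variation
  resolvable by central differences for field-accuracy comparisons;
  y0 = 1 is used to stress the integrator near the singularity.
- **curved** — principal eigenvector tangent to circles about the
  central z-axis; the oracle for the streamline baseline. On-axis
  voxels, where the tangent is undefined, get an isotropic fallback
  tensor and an invalid flag.
- **benchmark** — a homogeneous strongly anisotropic volume (default
  256×32×32, eigenvalues 9:1:1 along +x, a desk-scale rendition of the
  1024×64×64 / 2048-seed stress setup, which remains available behind
  `full=True`). Seeds are uniform in the box inset 2 voxels from every
  face, aimed along +x or −x so that the straight-line travel distance
  max_steps·h stays inside the volume — by construction every fiber
  terminates at the step cap, putting the tracker under maximum
  sustained load. An optional Gaussian tensor perturbation exists for
  robustness experiments and defaults off.

What the phantoms do *not* emulate: measurement noise, partial-volume
averaging, crossing or kissing fibers, anatomical geometry, or
non-identity world affines. Passing tests therefore demonstrate the
numerical correctness of the machinery, not clinical validity on real
brain data.

## Numerical characterization and known limits

- Trilinear interpolation reproduces voxel values exactly at lattice
  points and trilinear-in-coordinates fields to ~10⁻¹² relative.
- Central differences are exact for component-wise linear fields and
  second order on smooth ones (measured order ≈ 2.0 under grid
  refinement of the half-plane metric).
- The dominant error source on coarse grids is the derivative field
  where the metric is strongly curved: on the unit-spacing half-plane
  with y0 = 1, the central difference of y⁻² is ~78 % high in magnitude
  at y = 2, so a long fiber descending to small y accumulates a ~3.5 %
  circle residual (endpoint ~0.6 voxels from the closed form). A
  tight-tolerance adaptive reference integration of the *same
  interpolated field* lands at the same point, confirming this is field
  discretization, not integrator error; on the analytic field the
  endpoint error at the same step size is ~3×10⁻⁵ voxels. Second-order
  one-sided boundary stencils were evaluated and change the result by
  < 10⁻⁴ voxels, so the simpler first-order boundary treatment is kept.
- Degenerate (non-invertible) tensors are regularized, flagged, and
  never abort a volume; the phantoms produce none except the curved
  phantom's on-axis voxels.

## Cost model

The memory-traffic functions reproduce the data-layout arithmetic of
the per-fiber tracking loop: 4 tensors × 6 unique components × 4 bytes
= 96 bytes per voxel; per step, a fiber reads the 8-voxel neighborhood
of all four fields (768 bytes) and writes one 3-component single-
precision point (12 bytes); a 2048-fiber × 4096-step run therefore
moves 780 × 2048 × 4096 ≈ 6.54 GB (GB = 10⁹ bytes throughout). The
model describes the algorithm's data path on a streaming architecture;
it is explicitly not a claim about this implementation's cache
behavior, and no timing or throughput is modeled.

## Problem sizes

The test suite and acceptance script use desk-scale problem sizes
chosen to characterize each property cleanly: 64-row half-plane grids,
1000-step oracle traces, a 256×32×32 / 128-seed / 512-step benchmark,
and refinement studies over spacings 1–0.25. The full-size benchmark
preset is available but not exercised by default.
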