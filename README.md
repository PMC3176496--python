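# geotract

Geodesic ray-tracing fiber tracking for diffusion tensor imaging (DTI).

In DTI, water diffusion in each voxel is described by a symmetric
positive-definite 3×3 tensor *D* whose principal eigenvector follows the
local white-matter fiber orientation. The classic *streamline* method
integrates that eigenvector field directly, which is fast but fragile in
noisy or crossing-fiber regions. This package implements the geodesic
alternative: equip the volume with the Riemannian metric

    G = D⁻¹,

so that moving along high-diffusion directions is cheap, and model fibers
as geodesics of that metric. A geodesic x(τ) minimizes the Riemannian
length L(x) = ∫ √(ẋᵀ G ẋ) dτ and satisfies

    ẍ^γ + Σ_αβ Γ^γ_αβ ẋ^α ẋ^β = 0,
    Γ^γ_αβ = ½ Σ_σ g^{γσ} ( ∂_α g_βσ + ∂_β g_ασ − ∂_σ g_αβ ),

where g_ij are the components of G and g^{ij} those of D. Tracing many
geodesics per seed in many directions and filtering them through a target
region yields candidate connections between two areas (region-to-region
connectivity), including multiple distinct routes where they exist.

What the package provides:

- **tensor fields** (`geotract.tensors`) — tensor volumes, voxel-wise SPD
  inversion with regularization of degenerate tensors, central-difference
  derivative fields of the metric, and trilinear interpolation of the four
  per-voxel tensors the tracker needs (D and the three derivatives of G);
- **geodesic core** (`geotract.geodesic`) — the 18 unique Christoffel
  symbols, the geodesic ODE right-hand side, Euler and midpoint (RK2)
  steppers, and the discrete Riemannian length;
- **tracking** (`geotract.tracking`) — seed/direction generation, per-fiber
  tracing with volume-exit and step-cap stopping rules, a vectorized batch
  tracer whose output is bitwise independent of batching, and the
  eigenvector-streamline baseline;
- **connectivity** (`geotract.connectivity`) — region filtering and
  score-based ranking of fibers;
- **phantoms** (`geotract.phantoms`) — synthetic volumes with known
  geometry (homogeneous, hyperbolic half-plane with closed-form geodesics,
  tangential/curved, stress benchmark);
- **cost model** (`geotract.costmodel`) — the byte-level memory-traffic
  arithmetic of the tracking data layout;
- **I/O + CLI** (`geotract.io`, `geotract.cli`) — NIfTI tensor volumes
  (two component-order dialects), TrackVis TRK and JSON fiber files, and
  the `geotract` command with `phantom`, `precompute`, `track`, `filter`,
  `rank`, `costmodel` and `inspect` subcommands.

## Worked example

The hyperbolic half-plane phantom has the metric diag(y⁻², y⁻², 1), whose
geodesics are exact semicircles centered on y = 0 — a closed-form oracle
for the whole pipeline. Launch a fiber horizontally at height y = 16:

```python
import numpy as np
from geotract import (GridFieldProvider, HalfPlaneProvider, TrackingConfig,
                      precompute, trace_fiber)
from geotract.phantoms import make_halfplane

vol = make_halfplane((64, 64, 8), y0=1.0)          # D = diag(y², y², 1)
provider = GridFieldProvider(precompute(vol))       # grid-sampled fields
cfg = TrackingConfig(h=0.05, max_steps=1000, solver="rk2")
fiber = trace_fiber([32.0, 15.0, 4.0], [1.0, 0.0, 0.0], cfg, provider)

y = fiber.points[:, 1] + 1.0                        # physical height
resid = np.abs((fiber.points[:, 0] - 32)**2 + y**2 - 16.0**2) / 16.0**2
print(fiber.termination, fiber.n_points, f"{resid.max():.4f}")

exact = HalfPlaneProvider(y0=1.0)                   # analytic oracle field
fiber2 = trace_fiber([32.0, 15.0, 4.0], [1.0, 0.0, 0.0], cfg, exact)
ref = exact.geodesic_point(32.0, 16.0, 50.0); ref[2] = 4.0
print(f"{np.linalg.norm(fiber2.points[-1] - ref):.2e}")
```

prints

```
max_steps 1001 0.0352
3.16e-05
```

The fiber runs its full 1000 steps (1001 stored points) and follows the
semicircle of radius 16. On the grid-sampled field the worst relative
circle residual is 3.5 % — the discretization limit of central
differences of the y⁻² metric on a unit grid (see `docs/methods.md`) —
while on the analytic field the endpoint lands 3×10⁻⁵ voxels from the
closed form, i.e. the integrator itself is essentially exact at this
step size.

The same run from the shell:

```sh
geotract phantom --kind halfplane --dims 64,64,8 --y0 1 --out hp.nii.gz
geotract inspect --volume hp.nii.gz --point 32,15,4   # 18 symbols as JSON
geotract costmodel --fibers 2048 --steps 4096         # 96 B/voxel, 6.54 GB
```

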