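# Methods

## Geometry and field conventions

All volumes live on an axis-aligned grid: voxel index (i, j, k) has
physical center `origin + (i, j, k) ⊙ spacing` in mm; arrays are stored
in (x, y, z) index order. Files with a non-identity direction matrix are
rejected rather than silently resampled, so the index ↔ mm mapping is a
single unambiguous routine shared by every type. NIfTI headers store
geometry as float32; on read, spacing and origin are canonicalized to
the shortest decimal that round-trips through float32, so a 0.86 mm
spacing compares equal across NIfTI and MetaImage.

A `VectorField` is always a *pull-back* displacement in physical mm: a
value u at output location x means "sample the source at x + u". This
makes warping a single trilinear resampling pass,

    output(x) = source(x + u(x)),

and makes the compositive accumulation of two fields well defined (see
below). "Forward" and "inverse" refer to which image plays fixed vs.
moving, never to push-forward semantics. Samples falling outside the
voxel-center extent of the source take a fill value, −1000 HU (air) by
default. Masks are warped as 0/1 volumes and thresholded at 0.5, with
exactly 0.5 mapping to foreground for determinism.

## Landmark interpolants

Given source points SP and target points TP (mm), a displacement
function is fitted so that f(SP_i) = TP_i − SP_i exactly.

**Thin-plate spline (global).** The 3-D biharmonic kernel U(r) = r is
used (the 2-D r² log r kernel does not apply in 3-D; 2-D deformation is
out of scope). The linear system couples an affine part (3×4) with
kernel weights subject to the orthogonality side conditions Σw = 0 and
Σ w ⊗ c = 0; with zero regularization the interpolation is exact and
any landmark data consistent with an affine map is reproduced with
identically zero bending weights. At least 4 non-coplanar landmarks are
required for the affine part to be identifiable; degenerate
configurations raise a singular-system error. An optional ridge term
(`regularization`, mm-scale, default 0) is added to the kernel diagonal
for near-degenerate sets, trading exactness for conditioning.

**Compactly supported RBF (local).** The Wendland C² function
ψ(r) = (1 − r/a)⁴₊ (4r/a + 1) with support radius a (mm; the "scaling
parameter" controlling locality). The kernel matrix is positive
definite, so the system is solved without a polynomial term by default —
this is what makes the compact-support guarantee exact: the displacement
is identically zero at any point ≥ a from all control points. An affine
part can be requested explicitly, at the cost of that guarantee. The
specific Wendland member and the absence of a default affine term are
this package's choices; ψ₃,₁ is the standard C² kernel for 3-D
scattered-data interpolation.

**Anchors.** A landmark with SP = TP pins the displacement to zero
there. `add_default_anchors` places eight anchors at the grid's corner
voxels (idempotently), preventing excessive warping of the volume
border. Global + local deformations are combined by *voxel-wise
addition* of the two sampled fields and applied to the image once.

## Field inversion

The inverse displacement g of a field f satisfies g(x) = −f(x + g(x));
it is computed by fixed-point iteration g₀ = 0,
g_{n+1}(x) = −f(x + g_n(x)), sampling f trilinearly with edge-clamped
extrapolation. Defaults: stopping tolerance 0.01 mm on the max voxel
update, at most 50 iterations. The iteration is a contraction when
‖∇f‖ < 1 (guaranteed for diffeomorphic fields of moderate amplitude);
non-convergence is reported as a status flag plus a warning, never an
exception, and the achieved residual is always attached to the result.
The inversion method itself is a design choice of this package.

## Field metrics

**Compositive accumulation.** `compose(left, right)(x) = right(x) +
left(x + right(x))`, the left field sampled trilinearly with
edge-clamped extrapolation so the composition is total. Under pull-back
semantics, warping once by the composite equals warping by `left` then
`right` up to interpolation error (property-tested on smooth fields).

**Inverse-consistency error.** The per-voxel Euclidean norm (mm) of the
composition of a forward field with a putative inverse; identically
zero for true inverses. Because a single reported millimetre figure
does not identify its statistic, the summary always reports mean
(headline), max and 95th percentile, over the whole grid or a caller-
supplied region. Voxels near the boundary pick up extrapolation
residue, so interior-restricted summaries are used in validation.

**Jacobian determinant.** det(I + ∇u) of the total map, computed with
spacing-aware central differences (one-sided on faces), so the identity
field maps to exactly 1. Central differencing is exact for affine
fields and second-order accurate otherwise (convergence order ≥ 1.9
verified against closed forms under grid refinement). A negative
minimum anywhere flags folding — a physically unachievable organ
deformation.

**Harmonic energy.** Per-voxel ‖∇u‖²_F of the displacement,
dimensionless, summarized by its mean; no ½ factor — the convention
used in the registration literature this metric comes from. It is zero
for any rigid translation, equals ‖A‖²_F for a linear field u = A(x−c),
and is invariant under adding a constant to the field.

## Structure and image metrics

Surfaces are the physical centers of foreground voxels with at least
one face-adjacent background or out-of-grid neighbor; no sub-voxel
meshing. This voxel-surface model is deterministic and directly
checkable against a brute-force 6-neighborhood scan; the distance
computation uses a KD-tree and is verified against all-pairs
enumeration to 1e-9 mm in tests.

- **Dice** 2|A∩B|/(|A|+|B|); empty-vs-empty defined as 1, empty vs
  non-empty as 0 (totality with the least-surprise reading).
- **Hausdorff distance**: symmetrized maximum of nearest-point
  distances, at the 100th percentile only (no HD95) — maximally
  sensitive to outliers by construction.
- **Average surface distance**: symmetrized as the mean over the union
  of both directed nearest-distance sets, which bounds both directed
  means; a directed variant is also available.
- **RMSE** √(mean (a−b)²) in HU, whole-volume or ROI-restricted. The
  per-voxel mean normalization is this package's choice. ROI
  restriction matters because a small global RMSE can hide large local
  errors inside organs.

The **structure audit** warps each original mask by the simulated
ground-truth field, then by the registration field under audit, and
compares with the original: a perfect registration returns every
structure to itself, and the residual Dice/Hausdorff/ASD quantify the
anatomical-correspondence error. Structures emptied by warping are
recorded as NaN with a warning entry rather than aborting the audit.

## Phantoms and analytic ground truth

The phantom generator renders geometric objects (sphere, ellipsoid,
box, cylinder along z) with specified HU on an air background; a voxel
belongs to an object when its center lies inside the analytic shape.
Optional additive Gaussian HU noise is seeded and off by default,
because every metric here is defined noise-free; real CT adds texture,
beam hardening and partial-volume effects that these phantoms do not
model, so passing tests demonstrate correctness of the computational
chain, not robustness to scanner physics. Landmarks are auto-placed at
the six axis-extreme surface points of each object (deterministic
order) plus the corner anchors, mimicking manual marker placement; the
default three-structure phantom (body ellipsoid 40 HU, tumor sphere
300 HU, airway cylinder −800 HU, 64³ at 2 mm) gives enough geometric
variety for warping and overlap metrics without patient data.

Analytic displacement fields provide exact oracles: translation,
uniform/axis-aligned scaling (closed-form inverse, constant Jacobian
and harmonic energy), a sinusoidal shear (closed-form pointwise
Jacobian; diffeomorphic iff 2πA/λ < 1), a Gaussian radial bump
(closed-form Jacobian via its radial/tangential eigenvalues; the
parameter bound |A| < σ keeps it comfortably diffeomorphic), and a
deliberately `folded` sinusoid (2πA/λ > 1) as the negative control for
the feasibility check. The sinusoidal and radial-bump inverses are
transcendental, so no closed-form inverse spec is attached for them —
the numerical inverter covers those cases; requesting the inverse of a
folded field raises an explicit non-invertibility error.

## Problem sizes and numerical tolerances

Validation runs use 48³–64³ grids at 2 mm spacing (≈ 100–126 mm cubes):
large enough that interior finite-difference stencils and voxelized
surfaces behave asymptotically, small enough for quick iteration.
Landmark interpolation exactness is asserted at 1e-6 mm, brute-force
metric agreement at 1e-9, Jacobian closed forms at 1e-9 on interior
voxels, and ICE for closed-form inverse pairs at 0.01 mm interior mean
— the same figure as the default inversion tolerance. Mask-recovery
Dice in the end-to-end audit is voxelization-limited (a 2 mm voxel
shell on a ~25 mm structure), hence the ≥ 0.95 expectation rather
than 1.

## Known limitations

- Axis-aligned grids only; DICOM / DICOM-RT parsing is out of scope
  (convert to NIfTI/MetaImage first).
- The toolkit audits DVFs; it does not perform registration.
- Surface metrics are voxel-based: they inherit half-voxel quantization
  and will differ from mesh-vertex implementations near that scale.
- Fixed-point inversion assumes a contractive (diffeomorphic, moderate
  gradient) field; heavily folded fields do not converge, and the
  result then carries the non-convergence flag.
- 2-D images are rejected; the engine is strictly 3-D.
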