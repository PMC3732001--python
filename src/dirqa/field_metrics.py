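"""Physical characteristics of deformation vector fields.

Compositive accumulation of two DVFs, inverse-consistency error (ICE),
the Jacobian determinant of the total map, and harmonic energy.

Conventions
-----------
* All fields are pull-back displacement maps in mm.
* ``compose_fields(left, right)(x) = right(x) + left(x + right(x))``,
  so that warping once by the composite equals warping by ``left``
  then by ``right``; the left field is sampled trilinearly with
  edge-clamped extrapolation.
* The Jacobian determinant is det(I + grad u) of the total map, so the
  identity field gives 1 everywhere, values > 1 mean local expansion,
  values in (0, 1) contraction, and negative values folding —
  a physically unachievable deformation.
* Harmonic energy is the squared Frobenius norm of the displacement
  Jacobian ||grad u||_F^2 (dimensionless, no 1/2 factor), summarized by
  its mean; it vanishes for rigid translations and grows with the
  nonlinearity/roughness of the warp.

Derivatives are spacing-aware central differences on interior voxels
and one-sided differences on the faces.
"""

from __future__ import annotations

import numpy as np

from .core import (
    BinaryMask,
    MetricReport,
    ScalarVolume,
    ValidationError,
    VectorField,
    _require_same_grid,
)
from .deform import sample_field

__all__ = [
    "compose_fields",
    "ice_map",
    "ice_summary",
    "jacobian_determinant",
    "harmonic_energy",
    "displacement_jacobian",
]


def compose_fields(left: VectorField, right: VectorField) -> VectorField:
    """Compositive accumulation of two displacement fields.

    A single warp by the returned field is equivalent to successive
    warping by ``left`` and then ``right`` (pull-back semantics):
    ``result(x) = right(x) + left(x + right(x))`` with the left field
    interpolated trilinearly at the displaced location.
    """
    _require_same_grid(left, right)
    grid = left.grid
    points = grid.voxel_centers().reshape(-1, 3)
    r = right.vectors.reshape(-1, 3)
    composed = r + sample_field(left, points + r)
    return VectorField(grid, composed.reshape(grid.size + (3,)))


def ice_map(forward: VectorField, inverse: VectorField) -> ScalarVolume:
    """Per-voxel inverse-consistency error (mm).

    The Euclidean norm of the compositive accumulation of the forward
    and putative inverse fields; identically zero when the two are true
    inverses of each other.
    """
    return compose_fields(forward, inverse).magnitude()


def _region_values(map_: ScalarVolume, region: BinaryMask | None) -> np.ndarray:
    if region is None:
        return map_.values.ravel()
    _require_same_grid(map_, region)
    if region.voxel_count == 0:
        raise ValidationError("empty region")
    return map_.values[region.values]


def ice_summary(
    map_: ScalarVolume, region: BinaryMask | None = None
) -> MetricReport:
    """Summarize an ICE map over a region (default: whole grid).

    The mean is the headline ICE statistic; the max and 95th percentile
    are always reported alongside because a single mm figure does not
    identify which statistic it is.
    """
    values = _region_values(map_, region)
    report = MetricReport()
    report.add("ice_mean", float(values.mean()), "mm")
    report.add("ice_max", float(values.max()), "mm")
    report.add("ice_p95", float(np.percentile(values, 95)), "mm")
    report.maps["ice"] = map_
    return report


def displacement_jacobian(f: VectorField) -> np.ndarray:
    """Gradient of the displacement, shape ``size + (3, 3)``.

    ``J[..., i, j] = d u_i / d x_j`` with spacing-aware central
    differences (one-sided on the faces).
    """
    if any(s < 3 for s in f.grid.size):
        raise ValidationError("Jacobian needs grid size >= 3 per axis")
    jac = np.empty(f.grid.size + (3, 3))
    for i in range(3):
        grads = np.gradient(f.vectors[..., i], *f.grid.spacing, edge_order=1)
        for j in range(3):
            jac[..., i, j] = grads[j]
    return jac


def jacobian_determinant(f: VectorField) -> ScalarVolume:
    """Per-voxel det(I + grad u) of the total deformation map.

    1 everywhere for the identity field; > 1 expansion, < 1 contraction,
    < 0 folding (a physically unachievable organ deformation).
    """
    jac = displacement_jacobian(f)
    total = jac + np.eye(3)
    return ScalarVolume(f.grid, np.linalg.det(total))


def harmonic_energy(
    f: VectorField, region: BinaryMask | None = None
) -> MetricReport:
    """Harmonic energy of a displacement field over a region.

    Per-voxel ``||grad u||_F^2`` summarized by its mean (headline value);
    the per-voxel map is attached to the report.  Zero for any constant
    translation; equals ``||A||_F^2`` for a linear field ``u = A(x - c)``.
    """
    jac = displacement_jacobian(f)
    density = ScalarVolume(f.grid, np.sum(jac**2, axis=(-2, -1)))
    values = _region_values(density, region)
    report = MetricReport()
    report.add("harmonic_energy_mean", float(values.mean()), "dimensionless")
    report.add("harmonic_energy_max", float(values.max()), "dimensionless")
    report.maps["harmonic_energy"] = density
    return report
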