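"""Synthetic deformation engine: landmark-driven TPS and CSRBF warps.

Two radial-basis interpolants turn paired landmarks (source points SP,
target points TP, both in mm) into a continuous displacement function:

* a thin-plate spline with the 3-D biharmonic kernel ``U(r) = r`` for
  global deformations — it interpolates the landmark displacements
  exactly and reproduces any affine map with zero bending; and
* a compactly supported radial basis function (Wendland
  ``psi(r) = (1 - r/a)^4_+ (4 r/a + 1)``, C^2) for local deformations
  whose influence vanishes beyond the support radius ``a``.

Anchor landmarks (SP == TP) pin the displacement to zero; by default
eight anchors sit at the corner voxels of the grid to prevent excessive
warping of the volume borders.  Fitted models are evaluated on a grid
to produce a VectorField, fields are combined by voxel-wise addition,
and images/masks are warped by a single pull-back trilinear resampling.
A numerical fixed-point iteration recovers the inverse field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import cdist

from .core import (
    BinaryMask,
    GridMismatchError,
    ImageGrid,
    LandmarkSet,
    ScalarVolume,
    ValidationError,
    VectorField,
    _require_same_grid,
)

__all__ = [
    "TPSModel",
    "CSRBFModel",
    "InversionResult",
    "add_default_anchors",
    "fit_tps",
    "fit_csrbf",
    "evaluate_field",
    "add_fields",
    "warp_image",
    "warp_mask",
    "edit_intensity",
    "invert_field",
    "sample_field",
]

AIR_HU = -1000.0  # CT background fill

_EVAL_CHUNK = 65536  # voxels per kernel-evaluation block (memory cap)


class SingularSystemError(np.linalg.LinAlgError):
    """The landmark interpolation system cannot be solved."""


def add_default_anchors(lm: LandmarkSet | None, grid: ImageGrid) -> LandmarkSet:
    """Append the 8 border anchor landmarks at the grid's corner voxels.

    Anchors (SP == TP) restrict the deformation to zero at the volume
    corners.  Corners already present as source points are not
    duplicated, so the operation is idempotent.
    """
    corners = grid.corner_points()
    if lm is None or len(lm) == 0:
        keep = np.ones(8, dtype=bool)
        base = None
    else:
        dists = cdist(corners, lm.source_points)
        keep = dists.min(axis=1) > 1e-9
        base = lm
    anchors = LandmarkSet(
        corners[keep], corners[keep], np.ones(int(keep.sum()), dtype=bool)
    ) if keep.any() else None
    if base is None:
        if anchors is None:
            return lm  # all corners already present
        return anchors
    return base if anchors is None else base.extend(anchors)


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    # 3-D biharmonic spline kernel
    return r


def _wendland(r: np.ndarray, a: float) -> np.ndarray:
    q = r / a
    return np.where(q < 1.0, (1.0 - q) ** 4 * (4.0 * q + 1.0), 0.0)


@dataclass
class TPSModel:
    """Fitted thin-plate spline displacement model.

    ``affine_part`` holds the affine component of the *displacement*
    (3x4: constant column then linear part); the corresponding mapping
    is identity plus this displacement.  The non-affine weights satisfy
    the orthogonality side conditions sum(w) = 0 and sum(w x c) = 0.
    """

    control_points: np.ndarray  # (n, 3) mm
    affine_part: np.ndarray  # (3, 4): [b | A]
    nonaffine_weights: np.ndarray  # (n, 3)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Displacement (mm) at physical points, shape (m, 3)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.affine_part[:, 0] + points @ self.affine_part[:, 1:].T
        for start in range(0, len(points), _EVAL_CHUNK):
            block = points[start : start + _EVAL_CHUNK]
            k = _tps_kernel(cdist(block, self.control_points))
            out[start : start + _EVAL_CHUNK] += k @ self.nonaffine_weights
        return out


@dataclass
class CSRBFModel:
    """Fitted compactly supported RBF displacement model.

    Without an affine part (the default) the displacement is exactly
    zero at any point at distance >= ``support_radius`` from every
    control point.
    """

    control_points: np.ndarray  # (n, 3) mm
    weights: np.ndarray  # (n, 3)
    support_radius: float  # mm
    affine_part: np.ndarray | None = None  # (3, 4) or None

    def displacement(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.affine_part is not None:
            out = self.affine_part[:, 0] + points @ self.affine_part[:, 1:].T
        else:
            out = np.zeros_like(points)
        for start in range(0, len(points), _EVAL_CHUNK):
            block = points[start : start + _EVAL_CHUNK]
            k = _wendland(cdist(block, self.control_points), self.support_radius)
            out[start : start + _EVAL_CHUNK] += k @ self.weights
        return out


def fit_tps(lm: LandmarkSet, regularization: float = 0.0) -> TPSModel:
    """Fit a 3-D thin-plate spline interpolating the landmark displacements.

    With ``regularization = 0`` the model reproduces TP - SP exactly at
    every source point; a positive value adds a ridge term to the kernel
    diagonal, trading exactness for robustness on near-degenerate sets.

    Raises
    ------
    SingularSystemError
        Fewer than 4 landmarks, a coplanar configuration (affine part
        unidentifiable), or a numerically singular system.
    """
    if regularization < 0:
        raise ValidationError("regularization must be >= 0")
    sp = lm.source_points
    n = len(sp)
    p = np.hstack([np.ones((n, 1)), sp])  # (n, 4)
    if n < 4 or np.linalg.matrix_rank(p) < 4:
        raise SingularSystemError(
            "TPS needs >= 4 non-coplanar landmarks for an identifiable affine "
            "part; add landmarks or use regularization with a richer set"
        )
    k = _tps_kernel(cdist(sp, sp)) + regularization * np.eye(n)
    system = np.zeros((n + 4, n + 4))
    system[:n, :n] = k
    system[:n, n:] = p
    system[n:, :n] = p.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = lm.displacements
    try:
        sol = np.linalg.solve(system, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(
            f"singular TPS system ({exc}); consider regularization > 0"
        ) from exc
    weights, affine = sol[:n], sol[n:]
    # affine rows of sol are [b; A^T]; assemble (3, 4) = [b | A]
    affine_part = np.hstack([affine[0][:, None], affine[1:].T])
    return TPSModel(sp.copy(), affine_part, weights)


def fit_csrbf(
    lm: LandmarkSet, support_radius: float, affine: bool = False
) -> CSRBFModel:
    """Fit a Wendland CSRBF interpolant with the given support radius (mm).

    The kernel matrix is positive definite, so no polynomial term is
    needed; ``affine=True`` adds one (at the cost of compact support of
    the total displacement).
    """
    if support_radius <= 0:
        raise ValidationError("support_radius must be > 0 mm")
    sp = lm.source_points
    n = len(sp)
    k = _wendland(cdist(sp, sp), support_radius)
    d = lm.displacements
    try:
        if affine:
            p = np.hstack([np.ones((n, 1)), sp])
            if n < 4 or np.linalg.matrix_rank(p) < 4:
                raise SingularSystemError(
                    "CSRBF with affine part needs >= 4 non-coplanar landmarks"
                )
            system = np.zeros((n + 4, n + 4))
            system[:n, :n] = k
            system[:n, n:] = p
            system[n:, :n] = p.T
            rhs = np.zeros((n + 4, 3))
            rhs[:n] = d
            sol = np.linalg.solve(system, rhs)
            weights, aff = sol[:n], sol[n:]
            affine_part = np.hstack([aff[0][:, None], aff[1:].T])
        else:
            weights = np.linalg.solve(k, d)
            affine_part = None
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(
            f"singular CSRBF kernel system ({exc}); support radius "
            f"{support_radius} mm may be too small for the landmark spacing"
        ) from exc
    model = CSRBFModel(sp.copy(), weights, float(support_radius), affine_part)
    residual = np.abs(model.displacement(sp) - d).max()
    if not np.isfinite(residual) or residual > 1e-5:
        raise SingularSystemError(
            f"CSRBF solve failed to interpolate (residual {residual:.3g} mm); "
            "increase the support radius"
        )
    return model


def evaluate_field(model: TPSModel | CSRBFModel, grid: ImageGrid) -> VectorField:
    """Sample a fitted model at every voxel center of ``grid``."""
    centers = grid.voxel_centers().reshape(-1, 3)
    vectors = model.displacement(centers).reshape(grid.size + (3,))
    return VectorField(grid, vectors)


def add_fields(f1: VectorField, f2: VectorField) -> VectorField:
    """Voxel-wise vector sum of two fields on the same grid.

    This is the simulator's way of combining a global (TPS) and a local
    (CSRBF) deformation into one field that is applied once; it is not
    functional composition (see ``dirqa.field_metrics.compose_fields``).
    """
    _require_same_grid(f1, f2)
    return VectorField(f1.grid, f1.vectors + f2.vectors)


def sample_field(f: VectorField, points: np.ndarray, mode: str = "nearest") -> np.ndarray:
    """Trilinearly sample a vector field at physical points (m, 3) -> (m, 3).

    Points beyond the grid extent are extrapolated with the nearest
    edge value (edge clamp), keeping composition and inversion total.
    """
    idx = f.grid.physical_to_index(points)
    coords = idx.T  # (3, m)
    out = np.empty_like(points, dtype=float)
    for c in range(3):
        out[:, c] = map_coordinates(f.vectors[..., c], coords, order=1, mode=mode)
    return out


def _pull_sample_scalar(
    values: np.ndarray, grid: ImageGrid, points: np.ndarray, fill_value: float
) -> np.ndarray:
    """Trilinear sample of a scalar array at physical points; outside the
    voxel-center extent the fill value is returned."""
    idx = grid.physical_to_index(points)
    upper = np.asarray(grid.size, dtype=float) - 1.0
    inside = np.all((idx >= 0.0) & (idx <= upper), axis=-1)
    sampled = map_coordinates(values, idx.T, order=1, mode="nearest")
    return np.where(inside, sampled, fill_value)


def warp_image(
    img: ScalarVolume, f: VectorField, fill_value: float = AIR_HU
) -> ScalarVolume:
    """Pull-back warp: ``output(x) = img(x + f(x))`` with trilinear sampling.

    Sample locations outside the image's physical extent take
    ``fill_value`` (default -1000 HU, air).
    """
    _require_same_grid(img, f)
    targets = f.grid.voxel_centers().reshape(-1, 3) + f.vectors.reshape(-1, 3)
    warped = _pull_sample_scalar(img.values, img.grid, targets, fill_value)
    return ScalarVolume(img.grid, warped.reshape(img.grid.size))


def warp_mask(mask: BinaryMask, f: VectorField) -> BinaryMask:
    """Warp a mask as a 0/1 volume and threshold at 0.5.

    An interpolated value of exactly 0.5 maps to foreground, which makes
    the result deterministic at the half-voxel boundary.
    """
    _require_same_grid(mask, f)
    as_scalar = ScalarVolume(mask.grid, mask.values.astype(float))
    warped = warp_image(as_scalar, f, fill_value=0.0)
    return BinaryMask(mask.grid, warped.values >= 0.5)


def edit_intensity(
    img: ScalarVolume, region: BinaryMask, delta: float
) -> ScalarVolume:
    """Add ``delta`` HU inside ``region``, leaving other voxels untouched.

    A negative delta carves a low-density object (e.g. a rectal gas
    pocket, or contrast removal) while preserving the underlying tissue
    structure, since the edit is purely additive.
    """
    _require_same_grid(img, region)
    out = img.values.copy()
    out[region.values] += delta
    return ScalarVolume(img.grid, out)


@dataclass
class InversionResult:
    """Outcome of numerical field inversion.

    ``residual`` is the max voxel update (mm) at the last iteration;
    non-convergence is reported here as ``converged=False`` (plus a
    warning), never as an exception.
    """

    field: VectorField
    residual: float
    iterations: int
    converged: bool


def invert_field(
    f: VectorField, tolerance: float = 0.01, max_iterations: int = 50
) -> InversionResult:
    """Numerically invert a displacement field by fixed-point iteration.

    Iterates ``g_{n+1}(x) = -f(x + g_n(x))`` from ``g_0 = 0`` until the
    max voxel update falls below ``tolerance`` (mm) or ``max_iterations``
    is reached.  Convergence requires the field to be diffeomorphic and
    contractive (callers may check min Jacobian > 0 first).
    """
    if tolerance <= 0 or max_iterations < 1:
        raise ValidationError("tolerance must be > 0 and max_iterations >= 1")
    centers = f.grid.voxel_centers().reshape(-1, 3)
    g = np.zeros_like(centers)
    residual = np.inf
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        g_new = -sample_field(f, centers + g)
        residual = float(np.abs(g_new - g).max())
        g = g_new
        if residual < tolerance:
            break
    converged = residual < tolerance
    if not converged:
        warnings.warn(
            f"field inversion did not converge in {max_iterations} iterations "
            f"(last update {residual:.4g} mm > tolerance {tolerance} mm)",
            RuntimeWarning,
            stacklevel=2,
        )
    inverse = VectorField(f.grid, g.reshape(f.grid.size + (3,)))
    return InversionResult(inverse, residual, iterations, converged)
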