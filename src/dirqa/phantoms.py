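"""Digital CT-like phantoms and analytic ground-truth deformation fields.

These stand in for patient CT series: geometric phantoms (spheres,
ellipsoids, boxes, cylinders on an air background) provide images and
structure masks with known geometry, and a family of analytic
displacement fields provides ground truth with closed-form Jacobian
determinant, harmonic energy (where it exists) and closed-form inverse
(where it exists), so every field metric can be checked against an
exact value rather than another numerical code.

Analytic field kinds
--------------------
translation      u(x) = t                          J = 1,    HE = 0
uniform_scaling  u(x) = (s - 1)(x - c)             J = s^3,  HE = 3(s-1)^2
axis_scaling     u_i(x) = (s_i - 1)(x_i - c_i)     J = Πs_i, HE = Σ(s_i-1)^2
sinusoidal       u_a(x) = A sin(2π x_a / λ)        J = 1 + (2πA/λ) cos(2π x_a/λ)
radial_bump      u(x) = (A/σ) e^{-r²/2σ²} (x - c)  J closed-form (see code)
folded           sinusoidal with 2πA/λ > 1 — deliberately non-invertible

The sinusoidal field is diffeomorphic iff 2πA/λ < 1; the ``folded``
kind requires the opposite and is the negative control for the
minimum-Jacobian feasibility check.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np

from .core import (
    BinaryMask,
    ImageGrid,
    LandmarkSet,
    ScalarVolume,
    ValidationError,
    VectorField,
)
from .deform import add_default_anchors

__all__ = [
    "PhantomObject",
    "PhantomSpec",
    "AnalyticFieldSpec",
    "FieldGroundTruth",
    "NonInvertibleFieldError",
    "make_phantom",
    "analytic_field",
    "default_phantom_spec",
]

_SHAPES = ("sphere", "ellipsoid", "box", "cylinder")
_FIELD_KINDS = (
    "translation",
    "uniform_scaling",
    "axis_scaling",
    "sinusoidal",
    "radial_bump",
    "folded",
)


class NonInvertibleFieldError(ValueError):
    """Requested the inverse of a field that folds space."""


@dataclass(frozen=True)
class PhantomObject:
    """One geometric insert: shape, center (mm), semi-axes (mm), HU, name.

    ``semi_axes`` are per-axis half-extents: a sphere uses a single
    radius (all three equal), a cylinder runs along z with semi-axes
    (rx, ry, half-height).
    """

    shape: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity: float
    name: str

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValidationError(f"unknown shape {self.shape!r}; one of {_SHAPES}")
        if any(s <= 0 for s in self.semi_axes):
            raise ValidationError("semi-axes must be positive")
        if self.shape == "sphere" and len(set(self.semi_axes)) != 1:
            raise ValidationError("a sphere needs equal semi-axes (its radius)")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean insidedness of physical points, shape (..., 3)."""
        rel = (np.asarray(points, dtype=float) - np.asarray(self.center)) / np.asarray(
            self.semi_axes
        )
        if self.shape in ("sphere", "ellipsoid"):
            return np.sum(rel**2, axis=-1) <= 1.0
        if self.shape == "box":
            return np.all(np.abs(rel) <= 1.0, axis=-1)
        # cylinder along z
        radial = rel[..., 0] ** 2 + rel[..., 1] ** 2 <= 1.0
        return radial & (np.abs(rel[..., 2]) <= 1.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a deterministic CT-like phantom."""

    grid: ImageGrid
    objects: tuple[PhantomObject, ...]
    background: float = -1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "objects", tuple(self.objects))
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        lo = np.asarray(self.grid.origin)
        hi = self.grid.index_to_physical(np.asarray(self.grid.size) - 1)
        for obj in self.objects:
            c, a = np.asarray(obj.center), np.asarray(obj.semi_axes)
            if np.any(c - a < lo) or np.any(c + a > hi):
                raise ValidationError(
                    f"object {obj.name!r} extends outside the grid physical extent"
                )


def make_phantom(
    spec: PhantomSpec,
) -> tuple[ScalarVolume, dict[str, BinaryMask], LandmarkSet]:
    """Render a phantom: HU volume, one mask per object, auto landmarks.

    Voxels belong to an object when their physical center lies inside
    its analytic shape; later objects overwrite earlier ones in the
    image.  Landmarks are the 6 axis-extreme surface points of each
    object (deterministic order: -x, +x, -y, +y, -z, +z per object,
    with TP initialized to SP) plus the 8 grid-corner anchors; callers
    displace the target points to define a deformation.
    """
    centers = spec.grid.voxel_centers()
    values = np.full(spec.grid.size, float(spec.background))
    masks: dict[str, BinaryMask] = {}
    for obj in spec.objects:
        inside = obj.contains(centers)
        values[inside] = obj.intensity
        masks[obj.name] = BinaryMask(spec.grid, inside)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    volume = ScalarVolume(spec.grid, values)

    points = []
    for obj in spec.objects:
        c = np.asarray(obj.center)
        for axis in range(3):
            for sign in (-1.0, +1.0):
                p = c.copy()
                p[axis] += sign * obj.semi_axes[axis]
                points.append(p)
    if points:
        pts = np.asarray(points)
        lm = LandmarkSet(pts, pts.copy(), np.zeros(len(pts), dtype=bool))
    else:
        lm = LandmarkSet.empty()
    lm = add_default_anchors(lm, spec.grid)
    return volume, masks, lm


@dataclass(frozen=True)
class AnalyticFieldSpec:
    """Parameters of one analytic displacement field (all lengths mm).

    Only the parameters relevant to ``kind`` are used: ``translation``
    for the translation kind; ``scale`` (scalar or per-axis triple) and
    ``center`` for the scalings; ``amplitude``, ``wavelength`` and
    ``axis`` for sinusoidal/folded; ``amplitude``, ``sigma`` and
    ``center`` for radial_bump.
    """

    kind: str
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float | tuple[float, float, float] = 1.0
    amplitude: float = 0.0
    wavelength: float = 1.0
    sigma: float = 1.0
    axis: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _FIELD_KINDS:
            raise ValidationError(
                f"unknown field kind {self.kind!r}; one of {_FIELD_KINDS}"
            )
        if self.kind in ("uniform_scaling", "axis_scaling"):
            scales = np.atleast_1d(np.asarray(self.scale, dtype=float))
            if np.any(scales <= 0):
                raise ValidationError("scale factors must be > 0 (diffeomorphic)")
        if self.kind == "sinusoidal":
            if self.wavelength <= 0:
                raise ValidationError("wavelength must be > 0")
            if 2 * np.pi * abs(self.amplitude) / self.wavelength >= 1:
                raise ValidationError(
                    "sinusoidal field requires 2*pi*amplitude/wavelength < 1 "
                    "(diffeomorphic range); use kind='folded' for a folding field"
                )
        if self.kind == "folded":
            if self.wavelength <= 0:
                raise ValidationError("wavelength must be > 0")
            if 2 * np.pi * abs(self.amplitude) / self.wavelength <= 1:
                raise ValidationError(
                    "folded field requires 2*pi*amplitude/wavelength > 1"
                )
        if self.kind == "radial_bump":
            if self.sigma <= 0:
                raise ValidationError("sigma must be > 0")
            # |grad u| stays < 1 everywhere when A < sigma (conservative)
            if abs(self.amplitude) >= self.sigma:
                raise ValidationError(
                    "radial_bump requires |amplitude| < sigma (diffeomorphic range)"
                )
        if self.axis not in (0, 1, 2):
            raise ValidationError("axis must be 0, 1 or 2")

    def _scales(self) -> np.ndarray:
        s = np.asarray(self.scale, dtype=float)
        if s.ndim == 0:
            s = np.repeat(s, 3)
        if self.kind == "uniform_scaling" and len(set(s.tolist())) != 1:
            raise ValidationError("uniform_scaling needs a single scale factor")
        return s

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Closed-form displacement (mm) at physical points (..., 3)."""
        x = np.asarray(points, dtype=float)
        if self.kind == "translation":
            return np.broadcast_to(np.asarray(self.translation), x.shape).copy()
        if self.kind in ("uniform_scaling", "axis_scaling"):
            return (self._scales() - 1.0) * (x - np.asarray(self.center))
        if self.kind in ("sinusoidal", "folded"):
            u = np.zeros_like(x)
            u[..., self.axis] = self.amplitude * np.sin(
                2 * np.pi * x[..., self.axis] / self.wavelength
            )
            return u
        # radial_bump
        rel = x - np.asarray(self.center)
        r2 = np.sum(rel**2, axis=-1, keepdims=True)
        g = (self.amplitude / self.sigma) * np.exp(-r2 / (2 * self.sigma**2))
        return g * rel

    def jacobian_determinant(self, points: np.ndarray) -> np.ndarray:
        """Closed-form det(I + grad u) at physical points (..., 3)."""
        x = np.asarray(points, dtype=float)
        base_shape = x.shape[:-1]
        if self.kind == "translation":
            return np.ones(base_shape)
        if self.kind in ("uniform_scaling", "axis_scaling"):
            return np.full(base_shape, float(np.prod(self._scales())))
        if self.kind in ("sinusoidal", "folded"):
            k = 2 * np.pi / self.wavelength
            return 1.0 + self.amplitude * k * np.cos(k * x[..., self.axis])
        rel = x - np.asarray(self.center)
        r2 = np.sum(rel**2, axis=-1)
        g = (self.amplitude / self.sigma) * np.exp(-r2 / (2 * self.sigma**2))
        # eigenvalues of I + grad u: (1+g) twice tangentially, 1+g(1-r^2/sigma^2) radially
        return (1.0 + g) ** 2 * (1.0 + g * (1.0 - r2 / self.sigma**2))

    def harmonic_energy_mean(self) -> float | None:
        """Closed-form spatial mean of ||grad u||_F^2, where constant."""
        if self.kind == "translation":
            return 0.0
        if self.kind in ("uniform_scaling", "axis_scaling"):
            return float(np.sum((self._scales() - 1.0) ** 2))
        return None  # position-dependent; no grid-free closed form

    def inverse(self) -> "AnalyticFieldSpec | None":
        """Closed-form inverse field spec, where one exists.

        Raises ``NonInvertibleFieldError`` for the folded kind; returns
        None for kinds whose inverse is not available in closed form
        (sinusoidal, radial_bump — the equation x + u(x) = y is
        transcendental).
        """
        if self.kind == "folded":
            raise NonInvertibleFieldError(
                "a folded field is non-invertible (Jacobian changes sign)"
            )
        if self.kind == "translation":
            return AnalyticFieldSpec(
                "translation",
                translation=tuple(-t for t in self.translation),
            )
        if self.kind in ("uniform_scaling", "axis_scaling"):
            inv = tuple(1.0 / s for s in self._scales())
            if self.kind == "uniform_scaling":
                return AnalyticFieldSpec(
                    "uniform_scaling", center=self.center, scale=inv[0]
                )
            return AnalyticFieldSpec("axis_scaling", center=self.center, scale=inv)
        return None


@dataclass
class FieldGroundTruth:
    """Exact reference quantities for a sampled analytic field."""

    spec: AnalyticFieldSpec
    jacobian: ScalarVolume
    min_jacobian: float
    harmonic_energy_mean: float | None
    inverse_spec: "AnalyticFieldSpec | None"
    displacement: Callable[[np.ndarray], np.ndarray] = dc_field(repr=False, default=None)


def analytic_field(
    spec: AnalyticFieldSpec, grid: ImageGrid
) -> tuple[VectorField, FieldGroundTruth]:
    """Sample an analytic field on a grid, with its exact ground truth.

    The ground truth carries the closed-form per-voxel Jacobian
    determinant, the closed-form harmonic-energy mean where one exists,
    and the closed-form inverse field spec where one exists (requesting
    it for the folded kind raises ``NonInvertibleFieldError`` at build
    time is avoided — the error surfaces when ``spec.inverse()`` is
    called).
    """
    centers = grid.voxel_centers()
    field = VectorField(grid, spec.displacement(centers))
    jac = spec.jacobian_determinant(centers)
    try:
        inverse_spec = spec.inverse()
    except NonInvertibleFieldError:
        inverse_spec = None
    gt = FieldGroundTruth(
        spec=spec,
        jacobian=ScalarVolume(grid, jac),
        min_jacobian=float(jac.min()),
        harmonic_energy_mean=spec.harmonic_energy_mean(),
        inverse_spec=inverse_spec,
        displacement=spec.displacement,
    )
    return field, gt


def default_phantom_spec(
    size: int = 64, spacing: float = 2.0, noise_sd: float = 0.0, seed: int = 0
) -> PhantomSpec:
    """A three-structure body-like phantom on an isotropic grid.

    A large soft-tissue ellipsoid ("body", 40 HU), a dense sphere
    ("tumor", 300 HU) and a low-density cylinder ("airway", -800 HU)
    on an air background — enough geometric variety to exercise warps,
    overlap metrics and intensity edits.
    """
    extent = (size - 1) * spacing
    c = extent / 2.0
    grid = ImageGrid((size, size, size), (spacing,) * 3, (0.0, 0.0, 0.0))
    objects = (
        PhantomObject(
            "ellipsoid", (c, c, c), (0.40 * extent, 0.33 * extent, 0.36 * extent),
            40.0, "body",
        ),
        PhantomObject(
            "sphere", (c + 0.12 * extent, c, c), (0.10 * extent,) * 3, 300.0, "tumor",
        ),
        PhantomObject(
            "cylinder", (c - 0.15 * extent, c, c),
            (0.05 * extent, 0.05 * extent, 0.22 * extent), -800.0, "airway",
        ),
    )
    return PhantomSpec(grid, objects, background=-1000.0, noise_sd=noise_sd, seed=seed)
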