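"""Core domain types shared by every dirqa module.

All geometry is axis-aligned: the physical center of voxel index
``(i, j, k)`` is ``origin + (i, j, k) * spacing`` in millimetres.
Arrays are stored in ``(i, j, k)`` index order (x, y, z), so
``values[i, j, k]`` is the voxel whose physical x-coordinate varies
with ``i``.  Displacements are physical-space vectors in mm and are
always pull-back maps: a field value ``u`` at output location ``x``
means "sample the source image at ``x + u``".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np


class GridMismatchError(ValueError):
    """Two objects that must share an ImageGrid do not."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class FormatError(ValueError):
    """A file's content does not match the expected format."""


@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned 3-D sampling geometry.

    Parameters
    ----------
    size : tuple of int
        Voxels per axis, each >= 2.
    spacing : tuple of float
        Voxel spacing per axis in mm, each > 0.
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    size: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "size", tuple(int(s) for s in self.size))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.size) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValidationError("ImageGrid is strictly 3-D")
        if any(s < 2 for s in self.size):
            raise ValidationError(f"all grid sizes must be >= 2, got {self.size}")
        if any(sp <= 0 for sp in self.spacing):
            raise ValidationError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.size

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to mm coordinates."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        """Map mm coordinates, shape (..., 3), to continuous voxel indices."""
        point = np.asarray(point, dtype=float)
        return (point - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """Physical centers of every voxel, shape ``size + (3,)`` in mm."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.size[a])
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def corner_points(self) -> np.ndarray:
        """Physical centers of the 8 corner voxels, shape (8, 3)."""
        lo = np.asarray(self.origin)
        hi = self.index_to_physical(np.asarray(self.size) - 1)
        corners = []
        for cx in (lo[0], hi[0]):
            for cy in (lo[1], hi[1]):
                for cz in (lo[2], hi[2]):
                    corners.append((cx, cy, cz))
        return np.asarray(corners)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


def _require_same_grid(a: Any, b: Any) -> None:
    if a.grid != b.grid:
        raise GridMismatchError(
            f"grids differ: {a.grid} vs {b.grid}"
        )


@dataclass
class ScalarVolume:
    """Scalar intensity volume (HU for CT-like data) on an ImageGrid."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.size:
            raise ValidationError(
                f"value array shape {self.values.shape} != grid size {self.grid.size}"
            )

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy())


@dataclass
class VectorField:
    """Per-voxel 3-vector displacement in physical mm (a DVF)."""

    grid: ImageGrid
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.shape != self.grid.size + (3,):
            raise ValidationError(
                f"vector array shape {self.vectors.shape} != grid size + (3,) "
                f"= {self.grid.size + (3,)}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("vector field contains non-finite entries")

    @classmethod
    def zeros(cls, grid: ImageGrid) -> "VectorField":
        return cls(grid, np.zeros(grid.size + (3,)))

    def magnitude(self) -> ScalarVolume:
        """Per-voxel Euclidean norm (mm) as a ScalarVolume."""
        return ScalarVolume(self.grid, np.linalg.norm(self.vectors, axis=-1))

    def copy(self) -> "VectorField":
        return VectorField(self.grid, self.vectors.copy())


@dataclass
class BinaryMask:
    """Boolean structure mask on an ImageGrid."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.grid.size:
            raise ValidationError(
                f"mask shape {self.values.shape} != grid size {self.grid.size}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.grid, self.values.copy())


@dataclass
class LandmarkSet:
    """Paired source (SP) and target (TP) points in mm with anchor flags.

    An anchor is a landmark with SP == TP; it pins the deformation to
    zero at that location.
    """

    source_points: np.ndarray
    target_points: np.ndarray
    anchor_flags: np.ndarray

    def __post_init__(self) -> None:
        self.source_points = np.atleast_2d(np.asarray(self.source_points, dtype=float))
        self.target_points = np.atleast_2d(np.asarray(self.target_points, dtype=float))
        self.anchor_flags = np.atleast_1d(np.asarray(self.anchor_flags, dtype=bool))
        n = len(self.source_points)
        if self.source_points.shape != (n, 3) or self.target_points.shape != (n, 3):
            raise ValidationError("landmark points must be (n, 3) arrays")
        if len(self.anchor_flags) != n:
            raise ValidationError("anchor_flags length must match point count")
        if n < 1:
            raise ValidationError("at least one landmark is required")
        if n > 1:
            from scipy.spatial.distance import pdist

            if pdist(self.source_points).min() <= 1e-9:
                raise ValidationError("duplicated source points (distance <= 1e-9 mm)")
        bad = self.anchor_flags & (
            np.linalg.norm(self.source_points - self.target_points, axis=1) > 1e-9
        )
        if bad.any():
            raise ValidationError(
                f"anchor landmarks must have SP == TP; rows {np.where(bad)[0].tolist()} violate this"
            )

    def __len__(self) -> int:
        return len(self.source_points)

    @property
    def displacements(self) -> np.ndarray:
        """TP - SP, shape (n, 3), mm."""
        return self.target_points - self.source_points

    @classmethod
    def empty(cls) -> "LandmarkSet":
        ls = cls.__new__(cls)
        ls.source_points = np.zeros((0, 3))
        ls.target_points = np.zeros((0, 3))
        ls.anchor_flags = np.zeros(0, dtype=bool)
        return ls

    def extend(self, other: "LandmarkSet") -> "LandmarkSet":
        return LandmarkSet(
            np.vstack([self.source_points, other.source_points]),
            np.vstack([self.target_points, other.target_points]),
            np.concatenate([self.anchor_flags, other.anchor_flags]),
        )


@dataclass
class MetricReport:
    """Named scalar metrics with units, plus optional per-voxel maps.

    ``entries`` maps a metric name to ``{"value": float, "units": str}``;
    ``maps`` holds ScalarVolume references (e.g. an ICE map) that callers
    may write to disk separately.
    """

    entries: dict[str, dict[str, Any]] = field(default_factory=dict)
    maps: dict[str, ScalarVolume] = field(default_factory=dict)

    def add(self, name: str, value: float, units: str = "") -> None:
        v = float(value)
        self.entries[name] = {"value": v, "units": units}

    def add_entry(self, name: str, payload: dict[str, Any]) -> None:
        if "units" not in payload:
            raise ValidationError(f"entry {name!r} must carry a units string")
        self.entries[name] = payload

    def __getitem__(self, name: str) -> float:
        return self.entries[name]["value"]

    def to_json(self, ndigits: int = 6) -> str:
        """Serialize entries to JSON with fixed float precision (reproducible)."""

        def _round(obj: Any) -> Any:
            if isinstance(obj, float):
                return round(obj, ndigits)
            if isinstance(obj, dict):
                return {k: _round(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_round(v) for v in obj]
            return obj

        return json.dumps(_round(self.entries), indent=2, sort_keys=True, allow_nan=True)
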