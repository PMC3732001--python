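"""Anatomical-correspondence and image-similarity metrics.

Structure masks are compared with the Dice similarity coefficient,
the (symmetrized, 100th-percentile) Hausdorff distance, and the
average surface distance; images with (optionally ROI-restricted)
root-mean-square error in HU.  Surfaces are the physical centers of
foreground voxels with at least one face-adjacent background (or
out-of-grid) neighbor; distances are Euclidean point-set distances in
mm, computed with a KD-tree.

``structure_audit`` drives the virtual-QA comparison: each original
structure is warped by the simulated ground-truth field and then by a
registration field under audit; if the registration were perfect the
doubly-warped structure would coincide with the original, and the
residual mismatch quantifies registration quality.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

from .core import (
    BinaryMask,
    MetricReport,
    ScalarVolume,
    ValidationError,
    VectorField,
    _require_same_grid,
)
from .deform import warp_mask

__all__ = [
    "dice",
    "extract_surface",
    "hausdorff_distance",
    "average_surface_distance",
    "rmse",
    "structure_audit",
]


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|), in [0, 1].

    Defined as 1.0 when both masks are empty (perfect agreement) and
    0.0 when exactly one is empty.
    """
    _require_same_grid(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.values & b.values))
    return 2.0 * inter / (na + nb)


def extract_surface(m: BinaryMask) -> np.ndarray:
    """Surface points of a mask: centers (mm) of boundary voxels, (n, 3).

    A boundary voxel is foreground with >= 1 face-adjacent background or
    out-of-grid neighbor (6-connectivity).
    """
    if m.voxel_count == 0:
        raise ValidationError("cannot extract the surface of an empty mask")
    face_struct = generate_binary_structure(3, 1)
    interior = binary_erosion(m.values, structure=face_struct, border_value=0)
    boundary = m.values & ~interior
    idx = np.argwhere(boundary)
    return m.grid.index_to_physical(idx)


def _directed_nearest(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Distance (mm) from each point of A to its nearest point of B."""
    dists, _ = cKDTree(points_b).query(points_a, workers=-1)
    return dists


def hausdorff_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetrized Hausdorff distance (mm) between mask surfaces.

    The maximum over all surface points of the distance to the closest
    point on the other surface, taken in both directions; very sensitive
    to outliers by construction (100th percentile, no HD95 variant).
    """
    _require_same_grid(a, b)
    sa, sb = extract_surface(a), extract_surface(b)
    return float(
        max(_directed_nearest(sa, sb).max(), _directed_nearest(sb, sa).max())
    )


def average_surface_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetrized average surface distance (mm).

    Mean over the union of both directed nearest-surface distance sets
    (every point of each surface contributes one distance); 0 for
    identical masks, and bounded above by the Hausdorff distance.
    """
    _require_same_grid(a, b)
    sa, sb = extract_surface(a), extract_surface(b)
    d_ab = _directed_nearest(sa, sb)
    d_ba = _directed_nearest(sb, sa)
    return float(np.concatenate([d_ab, d_ba]).mean())


def directed_average_surface_distances(
    a: BinaryMask, b: BinaryMask
) -> tuple[float, float]:
    """Both directed ASD values (A→B mean, B→A mean) in mm."""
    sa, sb = extract_surface(a), extract_surface(b)
    return (
        float(_directed_nearest(sa, sb).mean()),
        float(_directed_nearest(sb, sa).mean()),
    )


def rmse(
    a: ScalarVolume, b: ScalarVolume, region: BinaryMask | None = None
) -> float:
    """Root-mean-square intensity difference (HU), optionally over an ROI.

    sqrt(mean (a - b)^2) over the region (whole grid when None); zero
    iff the images agree on every region voxel.  Restricting to organ
    ROIs exposes local mismatch that a whole-volume figure averages away.
    """
    _require_same_grid(a, b)
    diff = a.values - b.values
    if region is not None:
        _require_same_grid(a, region)
        if region.voxel_count == 0:
            raise ValidationError("empty region")
        diff = diff[region.values]
    return float(np.sqrt(np.mean(diff**2)))


_AUDIT_METRICS = ("dice", "hausdorff_mm", "avg_surface_distance_mm")


def structure_audit(
    structures: dict[str, BinaryMask],
    sim_field: VectorField,
    reg_field: VectorField,
) -> MetricReport:
    """Audit a registration DVF against ground truth on RT structures.

    Each structure is warped by the simulator field and then by the
    registration field; Dice, Hausdorff and average surface distance
    against the original quantify the residual mismatch (all three are
    perfect for an exact inverse).  The report holds per-structure
    entries plus the mean across structures; a structure emptied by
    warping has its distance metrics recorded as NaN with a warning
    entry rather than failing the audit.
    """
    if not structures:
        raise ValidationError("no structures to audit")
    report = MetricReport()
    per_metric: dict[str, list[float]] = {m: [] for m in _AUDIT_METRICS}
    warnings_list: list[str] = []
    for name, mask in structures.items():
        _require_same_grid(mask, sim_field)
        deformed = warp_mask(mask, sim_field)
        recovered = warp_mask(deformed, reg_field)
        d = dice(mask, recovered)
        if mask.voxel_count == 0 or recovered.voxel_count == 0:
            hd = asd = float("nan")
            warnings_list.append(
                f"structure {name!r} empty before or after warping; "
                "surface distances undefined"
            )
        else:
            hd = hausdorff_distance(mask, recovered)
            asd = average_surface_distance(mask, recovered)
        for metric, value in zip(_AUDIT_METRICS, (d, hd, asd)):
            units = "" if metric == "dice" else "mm"
            report.add(f"{name}.{metric}", value, units)
            if np.isfinite(value):
                per_metric[metric].append(value)
    for metric, values in per_metric.items():
        units = "" if metric == "dice" else "mm"
        mean = float(np.mean(values)) if values else float("nan")
        report.add(f"mean.{metric}", mean, units)
    if warnings_list:
        report.entries["warnings"] = {"value": warnings_list, "units": ""}
    return report
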