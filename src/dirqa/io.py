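"""Readers and writers for volumes, vector fields, masks, landmarks, reports.

Scalar volumes and 3-component displacement fields travel as NIfTI
(.nii/.nii.gz) or MetaImage (.mha/.mhd) through SimpleITK; landmarks as
CSV with header ``sx,sy,sz,tx,ty,tz,anchor`` (mm; anchor 0/1); metric
reports as JSON.  Only axis-aligned (identity-direction) grids are
accepted — files with a non-identity direction matrix are rejected so
that the mm <-> index mapping stays unambiguous.

On disk, scalars and field components are 32-bit float and masks 8-bit
unsigned; round-trips are exact at that stored precision.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import (
    BinaryMask,
    FormatError,
    ImageGrid,
    LandmarkSet,
    MetricReport,
    ScalarVolume,
    ValidationError,
    VectorField,
)

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")

LANDMARK_COLUMNS = ("sx", "sy", "sz", "tx", "ty", "tz", "anchor")


def _check_path(path: str | Path) -> str:
    path = str(path)
    name = path.lower()
    if not any(name.endswith(e) for e in _SUPPORTED_EXT):
        raise FormatError(
            f"unsupported extension for {path!r}; expected one of {_SUPPORTED_EXT}"
        )
    return path


def _read_sitk(path: str | Path) -> sitk.Image:
    path = _check_path(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path!r}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # ITK wraps all read failures in RuntimeError
        raise IOError(f"could not read {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(
            f"{path!r} is {img.GetDimension()}-D; only 3-D volumes are supported"
        )
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise FormatError(
            f"{path!r} has a non-identity direction matrix; "
            "only axis-aligned grids are supported"
        )
    return img


def _canonical_f32(value: float) -> float:
    """Shortest decimal that still round-trips through float32.

    NIfTI stores spacing/origin as float32; without this, a header
    spacing of 0.86 would read back as 0.8600000143051147 and exact
    grid comparisons across formats would spuriously fail.
    """
    return float(np.format_float_positional(np.float32(value), unique=True))


def _grid_of(img: sitk.Image, f32_header: bool) -> ImageGrid:
    spacing = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    if f32_header:
        spacing = tuple(_canonical_f32(v) for v in spacing)
        origin = tuple(_canonical_f32(v) for v in origin)
    return ImageGrid(size=tuple(img.GetSize()), spacing=spacing, origin=origin)


def _is_nifti(path: str) -> bool:
    name = str(path).lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _sitk_from(grid: ImageGrid, array_zyx: np.ndarray, vector: bool) -> sitk.Image:
    img = sitk.GetImageFromArray(array_zyx, isVector=vector)
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    return img


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a scalar volume; the grid reflects the file header exactly."""
    img = _read_sitk(path)
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise FormatError(
            f"{path!r} has {img.GetNumberOfComponentsPerPixel()} components; "
            "expected a scalar volume (use read_vector_field for DVFs)"
        )
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ScalarVolume(_grid_of(img, _is_nifti(path)), values)


def write_volume(volume: ScalarVolume, path: str | Path) -> None:
    """Write a scalar volume as 32-bit float."""
    path = _check_path(path)
    arr = volume.values.astype(np.float32).transpose(2, 1, 0)
    try:
        sitk.WriteImage(_sitk_from(volume.grid, arr, vector=False), path)
    except RuntimeError as exc:
        raise IOError(f"could not write {path!r}: {exc}") from exc


def read_vector_field(path: str | Path) -> VectorField:
    """Read a 3-component displacement field (mm, physical axes)."""
    img = _read_sitk(path)
    ncomp = img.GetNumberOfComponentsPerPixel()
    if ncomp != 3:
        raise FormatError(
            f"{path!r} has {ncomp} component(s) per voxel; a DVF needs exactly 3"
        )
    vec = sitk.GetArrayFromImage(img).transpose(2, 1, 0, 3)
    return VectorField(_grid_of(img, _is_nifti(path)), vec)


def write_vector_field(f: VectorField, path: str | Path) -> None:
    """Write a displacement field as a 3-component float32 vector volume."""
    path = _check_path(path)
    arr = f.vectors.astype(np.float32).transpose(2, 1, 0, 3)
    try:
        sitk.WriteImage(_sitk_from(f.grid, arr, vector=True), path)
    except RuntimeError as exc:
        raise IOError(f"could not write {path!r}: {exc}") from exc


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask (any nonzero voxel is foreground)."""
    vol = read_volume(path)
    return BinaryMask(vol.grid, vol.values != 0)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as 8-bit 0/1."""
    path = _check_path(path)
    arr = mask.values.astype(np.uint8).transpose(2, 1, 0)
    try:
        sitk.WriteImage(_sitk_from(mask.grid, arr, vector=False), path)
    except RuntimeError as exc:
        raise IOError(f"could not write {path!r}: {exc}") from exc


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read paired source/target landmarks from CSV.

    Required header: ``sx,sy,sz,tx,ty,tz,anchor`` (coordinates in mm,
    anchor 0 or 1).  Anchor rows must have identical source and target
    points; malformed rows raise with their line number.
    """
    path = str(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path!r}")
    sp, tp, anchors = [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path!r} is empty; header line required") from None
        header = [h.strip().lower() for h in header]
        if header != list(LANDMARK_COLUMNS):
            raise FormatError(
                f"{path!r}: expected header {','.join(LANDMARK_COLUMNS)}, "
                f"got {','.join(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 7:
                raise FormatError(
                    f"{path!r} line {lineno}: expected 7 fields, got {len(row)}"
                )
            try:
                values = [float(c) for c in row[:6]]
                anchor = int(row[6])
                if anchor not in (0, 1):
                    raise ValueError
            except ValueError:
                raise FormatError(
                    f"{path!r} line {lineno}: could not parse row {row!r}"
                ) from None
            sp.append(values[:3])
            tp.append(values[3:6])
            anchors.append(bool(anchor))
    if not sp:
        raise FormatError(f"{path!r} contains no landmark rows")
    try:
        return LandmarkSet(np.asarray(sp), np.asarray(tp), np.asarray(anchors))
    except ValidationError as exc:
        raise ValidationError(f"{path!r}: {exc}") from exc


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LANDMARK_COLUMNS)
        for s, t, a in zip(lm.source_points, lm.target_points, lm.anchor_flags):
            writer.writerow([repr(float(v)) for v in (*s, *t)] + [int(a)])


def write_report(report: MetricReport, path: str | Path, ndigits: int = 6) -> None:
    """Write a MetricReport's scalar entries as JSON (fixed precision)."""
    Path(path).write_text(report.to_json(ndigits=ndigits) + "\n")
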