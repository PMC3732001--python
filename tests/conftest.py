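"""Shared fixtures and independent brute-force oracles.

The oracle functions here re-derive each quantity by the most direct
(and slowest) route — explicit double loops, all-pairs distances,
point-by-point interpolation — so the vectorized implementations in
``dirqa`` are checked against code that shares none of their structure.
"""

from __future__ import annotations

import numpy as np
import pytest

from dirqa import BinaryMask, ImageGrid, LandmarkSet, ScalarVolume


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid() -> ImageGrid:
    return ImageGrid((12, 10, 11), (2.0, 2.5, 3.0), (-5.0, 0.0, 10.0))


@pytest.fixture
def iso_grid() -> ImageGrid:
    return ImageGrid((16, 16, 16), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))


def random_landmarks(
    rng: np.random.Generator, n: int, lo: float = 5.0, hi: float = 55.0,
    max_disp: float = 4.0,
) -> LandmarkSet:
    sp = rng.uniform(lo, hi, (n, 3))
    tp = sp + rng.uniform(-max_disp, max_disp, (n, 3))
    return LandmarkSet(sp, tp, np.zeros(n, dtype=bool))


def random_blob(
    rng: np.random.Generator, grid: ImageGrid, n_seeds: int = 3, radius: float = 8.0
) -> BinaryMask:
    """Union of a few random balls; non-empty by construction."""
    centers = grid.voxel_centers()
    mask = np.zeros(grid.size, dtype=bool)
    lo = np.asarray(grid.origin)
    hi = grid.index_to_physical(np.asarray(grid.size) - 1)
    for _ in range(n_seeds):
        c = rng.uniform(lo, hi)
        r = rng.uniform(0.4, 1.0) * radius
        mask |= np.sum((centers - c) ** 2, axis=-1) <= r**2
    if not mask.any():
        mask[tuple(s // 2 for s in grid.size)] = True
    return BinaryMask(grid, mask)


# ---------------------------------------------------------------- oracles


def tps_dense_solve(lm: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    """Assemble and solve the TPS system by explicit double loops.

    Returns (weights (n,3), affine (4,3) as [b; A^T]) for U(r) = r.
    """
    sp = lm.source_points
    n = len(sp)
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            k[i, j] = np.linalg.norm(sp[i] - sp[j])
    p = np.hstack([np.ones((n, 1)), sp])
    sys_ = np.zeros((n + 4, n + 4))
    sys_[:n, :n] = k
    sys_[:n, n:] = p
    sys_[n:, :n] = p.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = lm.displacements
    sol = np.linalg.solve(sys_, rhs)
    return sol[:n], sol[n:]


def tps_point_eval(
    weights: np.ndarray, affine: np.ndarray, sp: np.ndarray, x: np.ndarray
) -> np.ndarray:
    """Evaluate the double-loop TPS solution at one point."""
    u = affine[0] + affine[1:].T @ x
    for i in range(len(sp)):
        u = u + weights[i] * np.linalg.norm(x - sp[i])
    return u


def wendland_point_sum(
    weights: np.ndarray, sp: np.ndarray, a: float, x: np.ndarray
) -> np.ndarray:
    """Direct kernel-sum CSRBF evaluation at one point."""
    u = np.zeros(3)
    for i in range(len(sp)):
        r = np.linalg.norm(x - sp[i])
        q = r / a
        if q < 1.0:
            u = u + weights[i] * (1 - q) ** 4 * (4 * q + 1)
    return u


def trilinear_point(
    values: np.ndarray, grid: ImageGrid, point: np.ndarray, fill: float
) -> float:
    """Scalar trilinear interpolation at one physical point, from scratch."""
    idx = (np.asarray(point) - np.asarray(grid.origin)) / np.asarray(grid.spacing)
    if np.any(idx < 0) or np.any(idx > np.asarray(grid.size) - 1):
        return fill
    base = np.floor(idx).astype(int)
    base = np.minimum(base, np.asarray(grid.size) - 2)
    frac = idx - base
    total = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[0] if dx else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dz else 1 - frac[2])
                )
                total += w * values[base[0] + dx, base[1] + dy, base[2] + dz]
    return total


def surface_points_bruteforce(mask: BinaryMask) -> np.ndarray:
    """6-neighborhood boundary scan with explicit loops over voxels."""
    vals = mask.values
    pts = []
    nx, ny, nz = vals.shape
    for i, j, k in np.argwhere(vals):
        boundary = False
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ii, jj, kk = i + di, j + dj, k + dk
            if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz):
                boundary = True
                break
            if not vals[ii, jj, kk]:
                boundary = True
                break
        if boundary:
            pts.append(mask.grid.index_to_physical(np.array([i, j, k])))
    return np.asarray(pts)


def allpairs_surface_distances(
    a: BinaryMask, b: BinaryMask
) -> tuple[float, float]:
    """(Hausdorff, symmetrized ASD) via O(n^2) all-pairs distances."""
    sa = surface_points_bruteforce(a)
    sb = surface_points_bruteforce(b)
    d = np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1))
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    hausdorff = max(d_ab.max(), d_ba.max())
    asd = np.concatenate([d_ab, d_ba]).mean()
    return float(hausdorff), float(asd)


def smooth_random_field_array(
    rng: np.random.Generator, grid: ImageGrid, amplitude: float = 2.0
) -> np.ndarray:
    """A smooth, small-amplitude random displacement array (size + (3,)).

    Low-frequency sinusoids with random phases: infinitely smooth, so
    interpolation-based identities hold to tight tolerances.
    """
    centers = grid.voxel_centers()
    extent = (np.asarray(grid.size) - 1) * np.asarray(grid.spacing)
    u = np.zeros(grid.size + (3,))
    for comp in range(3):
        for axis in range(3):
            phase = rng.uniform(0, 2 * np.pi)
            u[..., comp] += (
                amplitude
                / 3.0
                * np.sin(2 * np.pi * centers[..., axis] / extent[axis] + phase)
            )
    return u


def interior(vol_values: np.ndarray, margin: int = 3) -> np.ndarray:
    sl = tuple(slice(margin, -margin) for _ in range(3))
    return vol_values[sl]
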