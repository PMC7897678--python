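"""Independent brute-force oracles used to cross-check the fast paths."""

from __future__ import annotations

import numpy as np


def brute_force_maxima(
    data: np.ndarray, radius_voxels: np.ndarray, noise_floor: float
) -> list[tuple[int, int, int]]:
    """All-neighborhood scan: voxels strictly greater than every voxel within
    the anisotropic ellipsoidal radius (in voxel units, (x, y, z) order)."""
    rx, ry, rz = radius_voxels
    nz, ny, nx = data.shape
    out = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = data[z, y, x]
                if v < noise_floor:
                    continue
                is_max = True
                for dz in range(-rz, rz + 1):
                    for dy in range(-ry, ry + 1):
                        for dx in range(-rx, rx + 1):
                            if dx == dy == dz == 0:
                                continue
                            if (dx / rx) ** 2 + (dy / ry) ** 2 + (dz / rz) ** 2 > 1.0:
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                                if data[zz, yy, xx] >= v:
                                    is_max = False
                                    break
                        if not is_max:
                            break
                    if not is_max:
                        break
                if is_max:
                    out.append((z, y, x))
    return out


def brute_force_pairs(
    coords_a: np.ndarray, coords_b: np.ndarray, semi_axes: np.ndarray
) -> set[tuple[int, int]]:
    """All-pairs double loop over the scaled-distance <= 2 predicate.

    Returns 0-based (i, j) index pairs.
    """
    sa = coords_a / semi_axes
    sb = coords_b / semi_axes
    pairs = set()
    for i in range(len(sa)):
        d = np.linalg.norm(sb - sa[i], axis=1)
        for j in np.nonzero(d <= 2.0)[0]:
            pairs.add((i, int(j)))
    return pairs


def brute_force_nearest(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """Per-A nearest-neighbor distances by an all-pairs double loop."""
    out = np.empty(len(coords_a))
    for i, p in enumerate(coords_a):
        out[i] = np.sqrt(((coords_b - p) ** 2).sum(axis=1)).min()
    return out


def points_in_spheres(
    coords: np.ndarray, centers: np.ndarray, radius: float
) -> np.ndarray:
    """Point-in-blob membership test over ground-truth sphere centers."""
    out = np.zeros(len(coords), dtype=bool)
    for i, p in enumerate(coords):
        for c in centers:
            if np.sqrt(((p - c) ** 2).sum()) <= radius:
                out[i] = True
                break
    return out
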