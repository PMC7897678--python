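"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* image arrays are ordered ``(z, y, x)`` (plane order of a TIFF stack);
* physical coordinate vectors are ordered ``(x, y, z)`` and expressed in nm;
* the physical coordinate of voxel index ``i`` along an axis is
  ``(i + 0.5) * voxel_size`` (voxel-center convention);
* intensities live on the 16-bit 0–65,535 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

INTENSITY_MAX = 65535.0


def _as_xyz(v: Sequence[float]) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector (x, y, z), got shape {a.shape}")
    return a


@dataclass
class VoxelGrid:
    """One channel of a 3D 16-bit image with physical voxel sizes.

    Parameters
    ----------
    data
        Intensity array, shape ``(nz, ny, nx)``, values in [0, 65535].
    voxel_size_nm
        Physical voxel size as an ``(x, y, z)`` 3-vector in nm.
    channel_name
        Name of the fluorescence channel the grid came from.
    """

    data: np.ndarray
    voxel_size_nm: np.ndarray
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("VoxelGrid.data must be 3-dimensional (z, y, x)")
        if min(self.data.shape) < 8:
            raise ValueError("VoxelGrid needs at least 8 voxels per axis")
        if self.data.min() < 0 or self.data.max() > INTENSITY_MAX:
            raise ValueError("intensities must lie within [0, 65535]")
        self.voxel_size_nm = _as_xyz(self.voxel_size_nm)
        if np.any(self.voxel_size_nm <= 0):
            raise ValueError("voxel sizes must be strictly positive")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def field_size_nm(self) -> np.ndarray:
        """Physical extents as an (x, y, z) vector in nm."""
        nz, ny, nx = self.data.shape
        return np.array([nx, ny, nz], dtype=float) * self.voxel_size_nm

    def voxel_centers_nm(self, indices_zyx: np.ndarray) -> np.ndarray:
        """Convert (n, 3) voxel indices in (z, y, x) order to (x, y, z) nm."""
        idx = np.atleast_2d(np.asarray(indices_zyx, dtype=float))
        xyz = idx[:, ::-1]  # -> (x, y, z)
        return (xyz + 0.5) * self.voxel_size_nm

    def voxel_of(self, coords_nm: np.ndarray) -> np.ndarray:
        """Voxel index (z, y, x) containing each (x, y, z) nm coordinate."""
        c = np.atleast_2d(np.asarray(coords_nm, dtype=float))
        idx = np.floor(c / self.voxel_size_nm).astype(int)
        nz, ny, nx = self.data.shape
        if np.any(idx < 0) or np.any(idx >= np.array([nx, ny, nz])):
            raise ValueError("coordinate outside the image field")
        return idx[:, ::-1]


@dataclass
class SpotSet:
    """Point objects (segmented spots or seeds) of one channel of one field.

    ``coords_nm`` is an (n, 3) array of (x, y, z) physical centroids.
    """

    coords_nm: np.ndarray
    peak_intensities: np.ndarray
    labels: np.ndarray
    source_channel: str
    field_size_nm: np.ndarray
    border_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords_nm = np.asarray(self.coords_nm, dtype=float).reshape(-1, 3)
        n = len(self.coords_nm)
        self.peak_intensities = np.asarray(self.peak_intensities, dtype=float).reshape(n)
        self.labels = np.asarray(self.labels, dtype=int).reshape(n)
        if len(np.unique(self.labels)) != n:
            raise ValueError("labels must be unique")
        self.field_size_nm = _as_xyz(self.field_size_nm)
        if n and (np.any(self.coords_nm < 0) or np.any(self.coords_nm > self.field_size_nm)):
            raise ValueError("centroids must lie within the field extents")
        if self.border_flags is not None:
            self.border_flags = np.asarray(self.border_flags, dtype=bool).reshape(n)

    def __len__(self) -> int:
        return len(self.coords_nm)

    def subset(self, mask: np.ndarray) -> "SpotSet":
        mask = np.asarray(mask)
        return SpotSet(
            coords_nm=self.coords_nm[mask],
            peak_intensities=self.peak_intensities[mask],
            labels=self.labels[mask],
            source_channel=self.source_channel,
            field_size_nm=self.field_size_nm,
            border_flags=None if self.border_flags is None else self.border_flags[mask],
        )

    @classmethod
    def from_coords(
        cls,
        coords_nm: np.ndarray,
        field_size_nm: Sequence[float],
        source_channel: str = "",
        peak_intensities: np.ndarray | None = None,
    ) -> "SpotSet":
        coords_nm = np.asarray(coords_nm, dtype=float).reshape(-1, 3)
        n = len(coords_nm)
        return cls(
            coords_nm=coords_nm,
            peak_intensities=(
                np.ones(n) if peak_intensities is None else peak_intensities
            ),
            labels=np.arange(1, n + 1),
            source_channel=source_channel,
            field_size_nm=_as_xyz(field_size_nm),
        )


@dataclass
class BinaryMask:
    """Boolean 3D mask aligned to a :class:`VoxelGrid`."""

    data: np.ndarray
    voxel_size_nm: np.ndarray
    source_threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("BinaryMask.data must be 3-dimensional (z, y, x)")
        self.voxel_size_nm = _as_xyz(self.voxel_size_nm)

    @property
    def field_size_nm(self) -> np.ndarray:
        nz, ny, nx = self.data.shape
        return np.array([nx, ny, nz], dtype=float) * self.voxel_size_nm

    def contains(self, coords_nm: np.ndarray) -> np.ndarray:
        """Point-in-mask lookup: True where the voxel holding the point is set."""
        c = np.atleast_2d(np.asarray(coords_nm, dtype=float))
        idx = np.floor(c / self.voxel_size_nm).astype(int)
        nz, ny, nx = self.data.shape
        if len(c) and (np.any(idx < 0) or np.any(idx >= np.array([nx, ny, nz]))):
            raise ValueError("coordinate outside the image field")
        if not len(c):
            return np.zeros(0, dtype=bool)
        return self.data[idx[:, 2], idx[:, 1], idx[:, 0]]


@dataclass
class Summary:
    """Mean ± SEM aggregate of per-image rows."""

    mean: float
    sem: float
    n: int


def summarize(rows: Sequence[float]) -> Summary:
    """Mean and standard error (sample SD / sqrt(n)) of per-image values.

    With a single row the SEM is undefined and reported as NaN.
    """
    arr = np.asarray(rows, dtype=float)
    if arr.size < 1:
        raise ValueError("summarize needs at least one row")
    if arr.size == 1:
        return Summary(mean=float(arr[0]), sem=float("nan"), n=1)
    return Summary(
        mean=float(arr.mean()),
        sem=float(arr.std(ddof=1) / np.sqrt(arr.size)),
        n=int(arr.size),
    )
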