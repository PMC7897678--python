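"""Synthetic 3D confocal fields, flow-cytometry events, and densitometry tables.

The generator emulates the acquisition regime of pseudo-super-resolution
confocal imaging of immunostained cortical neuropil: multichannel 16-bit
z-stacks (anisotropic voxels, 15–25 planes) in which each labeled protein
(e.g. C1q, NP1/2, synaptophysin) appears as a discrete sub-micron spot.
Spots are rendered as 3D Gaussian blobs truncated at 3σ on a constant
background with additive Gaussian read noise.  Every scene carries its
ground truth (centroids, planted colocalization links, mask membership) so
downstream segmentation, colocalization, null-model, and engulfment code can
be tested for parameter recovery without any real data.

Colocalized partner spots are displaced from their source by a jitter that is
isotropic in ellipsoid-scaled space (direction biased by the PSF anisotropy,
magnitude |N(0, jitter_sd)| truncated at 3·jitter_sd), so a single scalar
controls how tightly planted pairs overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import INTENSITY_MAX, BinaryMask, SpotSet, VoxelGrid

__all__ = [
    "ColocPlanEntry",
    "MaskPlan",
    "SceneSpec",
    "GroundTruth",
    "DensityError",
    "plant_ground_truth",
    "make_spot_scene",
    "make_mask_scene",
    "make_flow_events",
    "make_fraction_tables",
    "FRACTION_NAMES",
    "MARKER_COMPARTMENTS",
]


class DensityError(ValueError):
    """Raised when the requested spot density would merge planted blobs."""


def round_half_even(x: float) -> int:
    return int(np.rint(x))


@dataclass(frozen=True)
class ColocPlanEntry:
    """Plant a colocalized partner in ``target`` for a fraction of ``source``."""

    source: str
    target: str
    fraction: float
    jitter_sd_nm: float = 0.0


@dataclass(frozen=True)
class MaskPlan:
    """Solid high-intensity blobs emulating a microglial (Iba1-like) volume."""

    n_blobs: int = 4
    blob_radius_nm: float = 1500.0
    engulfed_fraction: float = 0.5
    channel: str = "tagged"
    intensity: float = 30000.0


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic multichannel field.

    Defaults follow confocal anisotropy (50 × 50 × 150 nm voxels) on a
    desk-scale 12.8 × 12.8 × 3 µm field (256 × 256 × 20 voxels); blob widths
    σ = (80, 80, 200) nm keep XY spot diameters below ~1 µm.
    """

    field_size_nm: tuple[float, float, float] = (12800.0, 12800.0, 3000.0)
    voxel_size_nm: tuple[float, float, float] = (50.0, 50.0, 150.0)
    channels: tuple[str, ...] = ("c1q", "np1", "syp")
    n_spots_per_channel: Mapping[str, int] = field(
        default_factory=lambda: {"c1q": 200, "np1": 200, "syp": 200}
    )
    spot_sigma_nm: tuple[float, float, float] = (80.0, 80.0, 200.0)
    peak_intensity_range: tuple[float, float] = (20000.0, 45000.0)
    background_level: float = 1000.0
    noise_sd: float = 300.0
    coloc_plan: tuple[ColocPlanEntry, ...] = ()
    mask_plan: MaskPlan | None = None
    min_separation_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fs = np.asarray(self.field_size_nm, float)
        vs = np.asarray(self.voxel_size_nm, float)
        if np.any(fs <= 0) or np.any(vs <= 0):
            raise ValueError("field and voxel sizes must be strictly positive")
        if np.any(np.round(fs / vs).astype(int) < 8):
            raise ValueError("field must span at least 8 voxels per axis")
        lo, hi = self.peak_intensity_range
        if not (0 <= lo <= hi <= INTENSITY_MAX):
            raise ValueError("peak_intensity_range must lie within [0, 65535]")
        if hi <= self.background_level:
            raise ValueError("peak intensities must exceed the background level")
        for entry in self.coloc_plan:
            if not 0.0 <= entry.fraction <= 1.0:
                raise ValueError("coloc fractions must lie in [0, 1]")
            if entry.jitter_sd_nm < 0:
                raise ValueError("jitter_sd_nm must be non-negative")
            for ch in (entry.source, entry.target):
                if ch not in self.channels:
                    raise ValueError(f"coloc_plan references unknown channel {ch!r}")
        if self.mask_plan is not None:
            if not 0.0 <= self.mask_plan.engulfed_fraction <= 1.0:
                raise ValueError("engulfed_fraction must lie in [0, 1]")

    @property
    def grid_shape_zyx(self) -> tuple[int, int, int]:
        fs = np.asarray(self.field_size_nm, float)
        vs = np.asarray(self.voxel_size_nm, float)
        nx, ny, nz = np.round(fs / vs).astype(int)
        return (int(nz), int(ny), int(nx))


@dataclass
class GroundTruth:
    """Planted truth of one scene: centroids, coloc links, mask membership."""

    centroids: dict[str, np.ndarray]
    links: list[tuple[str, int, str, int]]
    field_size_nm: np.ndarray
    mask_membership: dict[str, np.ndarray] = field(default_factory=dict)
    mask_blob_centers_nm: np.ndarray | None = None
    mask_blob_radius_nm: float | None = None

    def n(self, channel: str) -> int:
        return len(self.centroids[channel])

    def planted_fraction(self, source: str, target: str) -> float:
        k = sum(1 for s, _, t, _ in self.links if s == source and t == target)
        return k / self.n(source)

    def spot_set(self, channel: str) -> SpotSet:
        return SpotSet.from_coords(
            self.centroids[channel], self.field_size_nm, source_channel=channel
        )

    def linked_indices(self, source: str, target: str) -> list[tuple[int, int]]:
        return [(i, j) for s, i, t, j in self.links if s == source and t == target]


# ---------------------------------------------------------------------------
# centroid planting


def _check_density(spec: SceneSpec) -> None:
    # refuse scenes whose uniform density would, in expectation, put a
    # same-channel neighbor within one blob sigma of most spots
    fs = np.asarray(spec.field_size_nm, float)
    volume = float(np.prod(fs))
    sx, sy, sz = spec.spot_sigma_nm
    v_sigma = 4.0 / 3.0 * np.pi * sx * sy * sz
    for ch, n in spec.n_spots_per_channel.items():
        if n < 2:
            continue
        p_crowded = 1.0 - (1.0 - min(v_sigma / volume, 1.0)) ** (n - 1)
        if p_crowded > 0.5:
            raise DensityError(
                f"channel {ch!r}: {n} spots in {volume:.3g} nm^3 — expected "
                f"crowding probability {p_crowded:.2f} > 0.5 within one sigma"
            )


def _uniform_points(
    rng: np.random.Generator,
    n: int,
    field_size_nm: np.ndarray,
    min_sep_scaled: float,
    sigma: np.ndarray,
) -> np.ndarray:
    """Uniform points, optionally with a σ-scaled minimum pairwise separation."""
    if min_sep_scaled <= 0 or n < 2:
        return rng.uniform(0.0, field_size_nm, size=(n, 3))
    pts = np.empty((n, 3))
    k = 0
    attempts = 0
    max_attempts = 2000 * n
    while k < n:
        cand = rng.uniform(0.0, field_size_nm, size=3)
        if k:
            d2 = np.sum(((pts[:k] - cand) / sigma) ** 2, axis=1)
            if d2.min() < min_sep_scaled**2:
                attempts += 1
                if attempts > max_attempts:
                    raise DensityError(
                        "cannot satisfy min_separation_sigma at this density"
                    )
                continue
        pts[k] = cand
        k += 1
    return pts


def _scaled_jitter(
    rng: np.random.Generator, n: int, jitter_sd_nm: float, sigma_axes: np.ndarray
) -> np.ndarray:
    """Displacements isotropic in ellipsoid-scaled space, |Δ| ≤ 3·jitter_sd."""
    if jitter_sd_nm == 0:
        return np.zeros((n, 3))
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    w = v * sigma_axes  # bias direction by PSF anisotropy
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    r = np.abs(rng.normal(0.0, jitter_sd_nm, size=n))
    r = np.minimum(r, 3.0 * jitter_sd_nm)
    return w * r[:, None]


def plant_ground_truth(spec: SceneSpec, rng: np.random.Generator | None = None) -> GroundTruth:
    """Plant centroids and colocalization links without rendering any image.

    This is the cheap path used for parameter-recovery studies on full-size
    (~50 × 50 × 3 µm) fields where rendering voxel data would be wasteful.
    """
    _check_density(spec)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    fs = np.asarray(spec.field_size_nm, float)
    sigma = np.asarray(spec.spot_sigma_nm, float)

    centroids = {
        ch: _uniform_points(
            rng, spec.n_spots_per_channel[ch], fs, spec.min_separation_sigma, sigma
        )
        for ch in spec.channels
    }
    links: list[tuple[str, int, str, int]] = []
    next_slot = {ch: 0 for ch in spec.channels}
    for entry in spec.coloc_plan:
        n_src = spec.n_spots_per_channel[entry.source]
        n_tgt = spec.n_spots_per_channel[entry.target]
        k = round_half_even(entry.fraction * n_src)
        if next_slot[entry.target] + k > n_tgt:
            raise ValueError(
                f"coloc_plan overfills target channel {entry.target!r}: "
                f"needs {k} more partner slots"
            )
        src_idx = rng.choice(n_src, size=k, replace=False)
        jitter = _scaled_jitter(rng, k, entry.jitter_sd_nm, sigma)
        partners = centroids[entry.source][src_idx] + jitter
        # keep partners inside the field (reflect at the boundary)
        partners = np.abs(partners)
        partners = fs - np.abs(fs - partners)
        lo = next_slot[entry.target]
        centroids[entry.target][lo : lo + k] = partners
        links.extend(
            (entry.source, int(si), entry.target, lo + j)
            for j, si in enumerate(src_idx)
        )
        next_slot[entry.target] = lo + k
    return GroundTruth(centroids=centroids, links=links, field_size_nm=fs)


# ---------------------------------------------------------------------------
# rendering


def _render_blobs(
    shape_zyx: tuple[int, int, int],
    voxel_size_nm: np.ndarray,
    centroids_nm: np.ndarray,
    peaks: np.ndarray,
    sigma_nm: np.ndarray,
) -> np.ndarray:
    """Sum of 3D Gaussian blobs truncated at 3σ, evaluated at voxel centers."""
    img = np.zeros(shape_zyx, dtype=float)
    nz, ny, nx = shape_zyx
    dims = np.array([nx, ny, nz])
    half = np.ceil(3.0 * sigma_nm / voxel_size_nm).astype(int)
    for c, p in zip(centroids_nm, peaks):
        iv = np.floor(c / voxel_size_nm).astype(int)
        lo = np.maximum(iv - half, 0)
        hi = np.minimum(iv + half + 1, dims)
        ax = [(np.arange(lo[d], hi[d]) + 0.5) * voxel_size_nm[d] for d in range(3)]
        r2 = (
            ((ax[0] - c[0]) / sigma_nm[0])[None, None, :] ** 2
            + ((ax[1] - c[1]) / sigma_nm[1])[None, :, None] ** 2
            + ((ax[2] - c[2]) / sigma_nm[2])[:, None, None] ** 2
        )
        blob = p * np.exp(-0.5 * r2)
        blob[r2 > 9.0] = 0.0
        img[lo[2] : hi[2], lo[1] : hi[1], lo[0] : hi[0]] += blob
    return img


def make_spot_scene(
    spec: SceneSpec,
) -> tuple[dict[str, VoxelGrid], GroundTruth]:
    """Render every spot channel of a scene and return it with its truth.

    Each channel grid holds exactly ``n_spots`` Gaussian blobs at the planted
    centroids plus background and Gaussian read noise, clipped to the 16-bit
    range.  Identical specs (including seed) give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    truth = plant_ground_truth(spec, rng)
    vs = np.asarray(spec.voxel_size_nm, float)
    sigma = np.asarray(spec.spot_sigma_nm, float)
    shape = spec.grid_shape_zyx
    grids: dict[str, VoxelGrid] = {}
    for ch in spec.channels:
        pts = truth.centroids[ch]
        peaks = rng.uniform(*spec.peak_intensity_range, size=len(pts))
        img = _render_blobs(shape, vs, pts, peaks, sigma)
        img += spec.background_level
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=shape)
        np.clip(img, 0.0, INTENSITY_MAX, out=img)
        grids[ch] = VoxelGrid(data=img, voxel_size_nm=vs, channel_name=ch)
    return grids, truth


# ---------------------------------------------------------------------------
# microglia-like mask scenes


def _points_in_blobs(
    coords_nm: np.ndarray, centers_nm: np.ndarray, radius_nm: float
) -> np.ndarray:
    if len(coords_nm) == 0:
        return np.zeros(0, dtype=bool)
    d2 = np.sum(
        (coords_nm[:, None, :] - centers_nm[None, :, :]) ** 2, axis=2
    )
    return np.any(d2 <= radius_nm**2, axis=1)


def make_mask_scene(
    spec: SceneSpec,
) -> tuple[VoxelGrid, GroundTruth]:
    """Render a solid-blob mask channel plus centroids with known membership.

    The mask emulates an Iba1-stained microglial volume as ``n_blobs`` solid
    spheres of ``blob_radius_nm``.  For the designated channel,
    ``engulfed_fraction`` of its centroids are planted inside blobs (at most
    0.8 r from a blob center, so they sit clear of the boundary) and the rest
    strictly outside.
    """
    if spec.mask_plan is None:
        raise ValueError("SceneSpec.mask_plan is required for make_mask_scene")
    plan = spec.mask_plan
    rng = np.random.default_rng(spec.seed)
    fs = np.asarray(spec.field_size_nm, float)
    vs = np.asarray(spec.voxel_size_nm, float)
    r = plan.blob_radius_nm
    margin = np.minimum(r, fs / 2.0)
    centers = rng.uniform(margin, fs - margin, size=(plan.n_blobs, 3))

    n = spec.n_spots_per_channel[plan.channel]
    k = round_half_even(plan.engulfed_fraction * n)
    inside = np.empty((k, 3))
    for i in range(k):
        blob = rng.integers(plan.n_blobs)
        while True:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pt = centers[blob] + d * (0.8 * r) * rng.uniform() ** (1.0 / 3.0)
            if np.all(pt >= 0) and np.all(pt <= fs):
                inside[i] = pt
                break
    outside = np.empty((n - k, 3))
    j = 0
    while j < n - k:
        cand = rng.uniform(0.0, fs, size=3)
        d2 = np.sum((centers - cand) ** 2, axis=1)
        # keep clear of the boundary by one blob-rendering voxel diagonal
        if d2.min() > (r + float(np.linalg.norm(vs))) ** 2:
            outside[j] = cand
            j += 1
    pts = np.vstack([inside, outside])
    order = rng.permutation(n)
    pts = pts[order]

    shape = spec.grid_shape_zyx
    nz, ny, nx = shape
    zc = (np.arange(nz) + 0.5) * vs[2]
    yc = (np.arange(ny) + 0.5) * vs[1]
    xc = (np.arange(nx) + 0.5) * vs[0]
    img = np.zeros(shape, dtype=float)
    for c in centers:
        d2 = (
            ((xc - c[0]) ** 2)[None, None, :]
            + ((yc - c[1]) ** 2)[None, :, None]
            + ((zc - c[2]) ** 2)[:, None, None]
        )
        img[d2 <= r**2] = plan.intensity
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=shape)
    np.clip(img, 0.0, INTENSITY_MAX, out=img)

    membership = _points_in_blobs(pts, centers, r)
    truth = GroundTruth(
        centroids={plan.channel: pts},
        links=[],
        field_size_nm=fs,
        mask_membership={plan.channel: membership},
        mask_blob_centers_nm=centers,
        mask_blob_radius_nm=r,
    )
    grid = VoxelGrid(data=img, voxel_size_nm=vs, channel_name="iba1_mask")
    return grid, truth


# ---------------------------------------------------------------------------
# flow-cytometry event tables


@dataclass(frozen=True)
class FlowNoise:
    """Log-normal intensity model for negative and positive populations."""

    neg_mean_log: float = 4.0
    neg_sd_log: float = 0.5
    pos_mean_log: float = 7.5
    pos_sd_log: float = 0.4


def make_flow_events(
    n_events: int,
    frac_Apos: float,
    frac_Bpos: float,
    frac_double: float,
    channel_noise: FlowNoise | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic two-channel flow events with planted quadrant membership.

    Population counts are ``round(fraction * n_events)`` (half-to-even);
    positives draw from a high-mean log-normal and negatives from a low-mean
    log-normal per channel.  Columns: event_id, intensity_A, intensity_B,
    true_label (one of ``double``, ``A_only``, ``B_only``, ``neg``).
    """
    for name, f in (
        ("frac_Apos", frac_Apos),
        ("frac_Bpos", frac_Bpos),
        ("frac_double", frac_double),
    ):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if frac_double > min(frac_Apos, frac_Bpos):
        raise ValueError("frac_double cannot exceed min(frac_Apos, frac_Bpos)")
    noise = channel_noise or FlowNoise()
    rng = np.random.default_rng(seed)
    n_double = round_half_even(frac_double * n_events)
    n_Apos = round_half_even(frac_Apos * n_events)
    n_Bpos = round_half_even(frac_Bpos * n_events)
    n_A_only = n_Apos - n_double
    n_B_only = n_Bpos - n_double
    n_neg = n_events - n_double - n_A_only - n_B_only
    if min(n_A_only, n_B_only, n_neg) < 0:
        raise ValueError("inconsistent fractions after rounding")
    labels = np.array(
        ["double"] * n_double
        + ["A_only"] * n_A_only
        + ["B_only"] * n_B_only
        + ["neg"] * n_neg
    )
    a_pos = np.isin(labels, ["double", "A_only"])
    b_pos = np.isin(labels, ["double", "B_only"])

    def draw(positive: np.ndarray) -> np.ndarray:
        out = np.empty(n_events)
        out[positive] = rng.lognormal(
            noise.pos_mean_log, noise.pos_sd_log, positive.sum()
        )
        out[~positive] = rng.lognormal(
            noise.neg_mean_log, noise.neg_sd_log, (~positive).sum()
        )
        return out

    ia, ib = draw(a_pos), draw(b_pos)
    order = rng.permutation(n_events)
    return pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "intensity_A": ia[order],
            "intensity_B": ib[order],
            "true_label": labels[order],
        }
    )


# ---------------------------------------------------------------------------
# sub-synaptic fractionation densitometry tables

FRACTION_NAMES = ("SPM", "Cytoplasm", "Mitochondria")
MARKER_COMPARTMENTS = {"Psd95": 0, "Ldhb": 1, "Cox4": 2}


def make_fraction_tables(
    true_levels: Mapping[str, Sequence[float]],
    mixing: np.ndarray,
    noise_cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    marker_totals: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Densitometry table for compartment markers and proteins of interest.

    The observed signal of a protein in measured fraction *i* is
    ``sum_k mixing[i, k] * true_levels[k]`` times multiplicative log-normal
    noise of coefficient of variation ``noise_cv``.  Marker rows (Psd95, Ldhb,
    Cox4) are generated the same way from compartment-pure levels, i.e. the
    marker's total placed entirely in its own compartment.

    Returns a long table with columns (fraction, marker_or_protein, replicate,
    signal).
    """
    mixing = np.asarray(mixing, dtype=float)
    if mixing.shape != (3, 3) or np.any(mixing < 0):
        raise ValueError("mixing must be a non-negative 3x3 matrix")
    for name, lv in true_levels.items():
        if np.any(np.asarray(lv, float) < 0):
            raise ValueError(f"true levels for {name!r} must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))  # log-normal with unit mean
    mu = -0.5 * sigma**2

    rows = []

    def emit(name: str, levels: np.ndarray) -> None:
        clean = mixing @ levels
        for rep in range(1, n_replicates + 1):
            noisy = clean * (
                rng.lognormal(mu, sigma, 3) if noise_cv > 0 else 1.0
            )
            for frac_name, s in zip(FRACTION_NAMES, noisy):
                rows.append((frac_name, name, rep, float(s)))

    totals = marker_totals or {}
    for marker, comp in MARKER_COMPARTMENTS.items():
        pure = np.zeros(3)
        pure[comp] = totals.get(marker, 1.0)
        emit(marker, pure)
    for protein, lv in true_levels.items():
        emit(protein, np.asarray(lv, dtype=float))
    return pd.DataFrame(
        rows, columns=["fraction", "marker_or_protein", "replicate", "signal"]
    )
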