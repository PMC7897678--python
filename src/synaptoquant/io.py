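"""Plain-file interchange: TIFF stacks with a sidecar, SpotSet/result CSVs.

Each channel is written as one single-channel 16-bit TIFF in ZYX plane order
next to a YAML sidecar carrying voxel sizes (nm) and channel names, so any
16-bit stack with known voxel sizes can enter the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import SpotSet, VoxelGrid
from .synthetic import GroundTruth

SIDECAR_NAME = "scene_meta.yaml"


def write_scene(
    out_dir: str | Path, grids: dict[str, VoxelGrid], truth: GroundTruth | None = None
) -> Path:
    """Write one TIFF per channel plus the metadata sidecar (and truth CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {"channels": [], "voxel_size_nm": None}
    for name, grid in grids.items():
        tifffile.imwrite(
            out / f"{name}.tif", np.round(grid.data).astype(np.uint16)
        )
        meta["channels"].append(name)
        meta["voxel_size_nm"] = [float(v) for v in grid.voxel_size_nm]
    with open(out / SIDECAR_NAME, "w") as fh:
        yaml.safe_dump(meta, fh)
    if truth is not None:
        write_ground_truth(out / "ground_truth.csv", truth)
    return out


def read_scene(scene_dir: str | Path) -> dict[str, VoxelGrid]:
    scene_dir = Path(scene_dir)
    with open(scene_dir / SIDECAR_NAME) as fh:
        meta = yaml.safe_load(fh)
    vs = meta["voxel_size_nm"]
    return {
        name: VoxelGrid(
            data=tifffile.imread(scene_dir / f"{name}.tif").astype(float),
            voxel_size_nm=vs,
            channel_name=name,
        )
        for name in meta["channels"]
    }


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    link_of: dict[tuple[str, int], int] = {}
    for lid, (src, i, tgt, j) in enumerate(truth.links):
        link_of[(src, i)] = lid
        link_of[(tgt, j)] = lid
    rows = []
    for ch, pts in truth.centroids.items():
        member = truth.mask_membership.get(ch)
        for i, (x, y, z) in enumerate(pts):
            rows.append(
                {
                    "channel": ch,
                    "x_nm": x,
                    "y_nm": y,
                    "z_nm": z,
                    "link_id": link_of.get((ch, i), -1),
                    "in_mask": bool(member[i]) if member is not None else False,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_spots(path: str | Path, spots: SpotSet) -> None:
    n = len(spots)
    df = pd.DataFrame(
        {
            "label": spots.labels,
            "x_nm": spots.coords_nm[:, 0],
            "y_nm": spots.coords_nm[:, 1],
            "z_nm": spots.coords_nm[:, 2],
            "peak": spots.peak_intensities,
            "border_flag": (
                spots.border_flags
                if spots.border_flags is not None
                else np.zeros(n, dtype=bool)
            ),
        }
    )
    df.to_csv(path, index=False)


def read_spots(
    path: str | Path, field_size_nm, source_channel: str = ""
) -> SpotSet:
    df = pd.read_csv(path)
    return SpotSet(
        coords_nm=df[["x_nm", "y_nm", "z_nm"]].to_numpy(),
        peak_intensities=df["peak"].to_numpy(),
        labels=df["label"].to_numpy(),
        source_channel=source_channel,
        field_size_nm=field_size_nm,
        border_flags=df["border_flag"].to_numpy(dtype=bool),
    )


def write_json(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
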