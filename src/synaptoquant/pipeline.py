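"""End-to-end orchestration: segment -> colocalize -> null test -> engulfment.

A run is declared by a single :class:`RunConfig` (typically loaded from
YAML): a synthetic scene specification or an input manifest, per-channel
segmentation parameters, the colocalization ellipsoid, shuffle settings, and
a master seed from which every stochastic stage derives its own.  The report
carries per-image rows plus mean ± SEM aggregates, the resolved config, and
the package version, so every figure-style number traces to a per-image CSV.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colocalization import EllipsoidSpec, pairwise_coloc, synaptic_filter, triple_coloc
from .core import Summary, summarize
from .engulfment import count_engulfed, segment_mask
from .io import write_json, write_spots
from .segmentation import SegmentationParams, find_local_maxima, segment_spots
from .shuffle import compare_observed_vs_null, shuffle_envelope
from .synthetic import MaskPlan, SceneSpec, make_mask_scene, make_spot_scene

log = logging.getLogger("synaptoquant")

MAX_SEED = 2**31 - 1


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    scene: SceneSpec = field(default_factory=SceneSpec)
    n_fields: int = 3
    reference_channel: str = "c1q"
    partner_channel: str = "np1"
    synapse_channel: str = "syp"
    segmentation: dict[str, SegmentationParams] = field(default_factory=dict)
    ellipsoid: EllipsoidSpec = field(default_factory=EllipsoidSpec)
    shuffle_iterations: int = 100
    run_shuffle: bool = True
    mask_threshold: float | None = None
    seed: int = 0
    output_dir: str | None = None

    def params_for(self, channel: str) -> SegmentationParams:
        return self.segmentation.get(channel, SegmentationParams())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        if "scene" in raw:
            scene_raw = dict(raw["scene"])
            if "mask_plan" in scene_raw and scene_raw["mask_plan"] is not None:
                scene_raw["mask_plan"] = MaskPlan(**scene_raw["mask_plan"])
            for key in ("field_size_nm", "voxel_size_nm", "spot_sigma_nm",
                        "peak_intensity_range", "channels"):
                if key in scene_raw:
                    scene_raw[key] = tuple(scene_raw[key])
            kwargs["scene"] = SceneSpec(**scene_raw)
        if "segmentation" in raw:
            kwargs["segmentation"] = {
                ch: SegmentationParams(
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in p.items()
                    }
                )
                for ch, p in raw["segmentation"].items()
            }
        if "ellipsoid" in raw:
            kwargs["ellipsoid"] = EllipsoidSpec(**raw["ellipsoid"])
        for key in (
            "n_fields",
            "reference_channel",
            "partner_channel",
            "synapse_channel",
            "shuffle_iterations",
            "run_shuffle",
            "mask_threshold",
            "seed",
            "output_dir",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def resolved(self) -> dict[str, Any]:
        def enc(o: Any) -> Any:
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, np.ndarray):
                return o.tolist()
            return o

        return enc(dataclasses.asdict(self))


@dataclass
class RunReport:
    """Per-image rows, aggregates, and provenance of one pipeline run."""

    per_image: pd.DataFrame
    aggregates: dict[str, Summary]
    signed_rank: dict[str, Any] | None
    config: dict[str, Any]
    version: str = __version__


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages on ``n_fields`` synthetic fields.

    Per field: render the scene, segment every channel, run pairwise and
    synaptic-triple colocalization (reference vs partner), the shuffle-null
    envelope, and — when a mask threshold is configured and the scene has a
    mask plan — engulfment counting.  Deterministic under the master seed.
    """
    master = np.random.default_rng(config.seed)
    field_seeds = master.integers(0, MAX_SEED, size=config.n_fields)
    rows: list[dict[str, Any]] = []
    medians: list[tuple[float, float]] = []
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    for i, fseed in enumerate(field_seeds):
        spec = dataclasses.replace(config.scene, seed=int(fseed))
        grids, truth = make_spot_scene(spec)
        spots = {}
        for ch, grid in grids.items():
            params = config.params_for(ch)
            seeds = find_local_maxima(grid, params)
            spots[ch] = segment_spots(grid, seeds, params)
            log.info(
                "field %d channel %s: %d seeds, %d spots",
                i, ch, len(seeds), len(spots[ch]),
            )
            if out_dir:
                write_spots(out_dir / f"field{i:03d}_{ch}_spots.csv", spots[ch])
        ref = spots[config.reference_channel]
        par = spots[config.partner_channel]
        syp = spots[config.synapse_channel]
        pw = pairwise_coloc(ref, par, config.ellipsoid)
        tri = triple_coloc(ref, par, syp, config.ellipsoid)
        row: dict[str, Any] = {
            "field": i,
            "seed": int(fseed),
            "n_ref": len(ref),
            "n_partner": len(par),
            "n_syp": len(syp),
            "fraction_pairwise": pw.fraction_A_coloc,
            "fraction_triple": tri.fraction_A_coloc,
        }
        if config.run_shuffle:
            env = shuffle_envelope(
                ref, par, n_iterations=config.shuffle_iterations,
                seed=int(fseed) % MAX_SEED,
            )
            row["observed_median_nm"] = env.observed_median_nm
            row["null_median_nm"] = env.null_median_nm
            medians.append((env.observed_median_nm, env.null_median_nm))
        if config.mask_threshold is not None and config.scene.mask_plan is not None:
            mask_grid, mask_truth = make_mask_scene(spec)
            mask = segment_mask(mask_grid, config.mask_threshold)
            tagged_labels = {a for a, _ in pw.pair_list}
            syn_ref = synaptic_filter(ref, syp, config.ellipsoid)
            tagged = syn_ref.subset(np.isin(syn_ref.labels, list(tagged_labels)))
            np_flags = np.ones(len(tagged), dtype=bool)
            eng = count_engulfed(tagged, np_flags, mask)
            row["n_tagged_inside"] = eng.n_tagged_inside
            row["fraction_np_positive"] = eng.fraction_NP_positive
        rows.append(row)

    per_image = pd.DataFrame(rows)
    aggregates = {
        col: summarize(per_image[col].dropna().to_numpy())
        for col in per_image.columns
        if col not in ("field", "seed") and per_image[col].notna().any()
    }
    signed_rank = None
    if config.run_shuffle and len(medians) >= 6:
        sr = compare_observed_vs_null(medians)
        signed_rank = dataclasses.asdict(sr)

    report = RunReport(
        per_image=per_image,
        aggregates=aggregates,
        signed_rank=signed_rank,
        config=config.resolved(),
    )
    if out_dir:
        per_image.to_csv(out_dir / "per_image.csv", index=False)
        write_json(
            out_dir / "report.json",
            {
                "version": report.version,
                "aggregates": {
                    k: dataclasses.asdict(v) for k, v in aggregates.items()
                },
                "signed_rank": signed_rank,
                "config": report.config,
            },
        )
    return report
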