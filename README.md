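# synaptoquant

Quantitative image analysis for synaptic-protein colocalization studies.
The package targets the question of whether complement component C1q and
neuronal pentraxins (NP1/NP2) co-occur on the same synapses in brain tissue,
and whether microglia preferentially engulf C1q-tagged synapses that carry
NP1 — but every stage is generic over channels and works on any 3D
multichannel spot imagery.

It implements, as a tested and reusable pipeline:

- **3D spot segmentation** — local-maxima seeding within an anisotropic PSF
  radius followed by marker-based watershed with local-mean thresholding
  (hard floor on the 16-bit scale, 5,000–7,000 by convention), returning
  intensity-weighted centroids in physical nm.
- **Object-based colocalization** — two spots colocalize when ellipsoids
  drawn around their centroids (maximal lateral/axial sizes 200/500 nm,
  approximating the point spread function) overlap in 3D; equivalently,
  when the displacement scaled by the semi-axes satisfies
  ‖Δ/(a, a, c)‖ ≤ 2.  The *synaptic* triple analysis restricts both channels
  to spots colocalizing with a synapse marker (synaptophysin) first.
- **Monte Carlo shuffle null** — one channel's centroids are re-placed
  uniformly in the field (100 iterations); the observed cumulative frequency
  distribution (CFD) of minimal center-to-center distances is compared to
  the mean null CFD with a pointwise 95% envelope, and across images by a
  two-sided Wilcoxon signed-rank test on CFD medians.
- **Engulfment counting** — microglia reconstructed by intensity
  thresholding of the marker channel (cavities filled); the fraction of
  C1q-colocalized synaptic centroids inside the mask that also carry NP
  signal.
- **Flow-cytometry quadrants** — per-channel gates at the nearest-rank 99th
  percentile of a secondary-antibody control (1% false positive), quadrant
  percentages, and conditional co-occurrence ratios.
- **Fraction deconvolution** — a 3×3 linear system built from
  compartment-exclusive markers (Psd95 → synaptic plasma membrane,
  Ldhb → cytoplasm, Cox4 → mitochondria) converts per-fraction densitometry
  of a protein into per-compartment levels: solve *M·(x, y, z) = b*.
- **Synthetic scenes** — a first-class generator of 3D multichannel spot
  images, microglial masks, flow event tables, and densitometry tables with
  known ground truth (planted colocalization fractions, engulfed fractions,
  quadrant memberships, mixing matrices), so every stage is testable for
  parameter recovery without any raw data.

## Worked example

```python
import numpy as np
from synaptoquant import (
    SceneSpec, ColocPlanEntry, SegmentationParams, make_spot_scene,
    find_local_maxima, segment_spots, pairwise_coloc, triple_coloc,
    shuffle_envelope,
)

# a 12.8 x 12.8 x 3 um field; all C1q spots synaptic, 67% given an NP1
# partner jittered by 30 nm
spec = SceneSpec(
    n_spots_per_channel={"c1q": 200, "np1": 200, "syp": 250},
    coloc_plan=(
        ColocPlanEntry("c1q", "syp", 1.0, 0.0),
        ColocPlanEntry("c1q", "np1", 0.67, 30.0),
    ),
    seed=1,
)
grids, truth = make_spot_scene(spec)
params = SegmentationParams(threshold=6000.0, noise_floor=3000.0)
spots = {}
for ch, grid in grids.items():
    spots[ch] = segment_spots(grid, find_local_maxima(grid, params), params)
    print(f"{ch}: {len(spots[ch])} spots segmented ({truth.n(ch)} planted)")

pw = pairwise_coloc(spots["c1q"], spots["np1"])
tri = triple_coloc(spots["c1q"], spots["np1"], spots["syp"])
print(f"pairwise C1q-NP1 fraction: {pw.fraction_A_coloc:.3f}")
print(f"synaptic C1q-NP1 fraction: {tri.fraction_A_coloc:.3f}")

env = shuffle_envelope(spots["c1q"], spots["np1"], n_iterations=100, seed=1)
print(f"observed median distance: {env.observed_median_nm:.0f} nm")
print(f"mean shuffled median:     {env.null_median_nm:.0f} nm")
```

prints

```
c1q: 196 spots segmented (200 planted)
np1: 196 spots segmented (200 planted)
syp: 243 spots segmented (250 planted)
pairwise C1q-NP1 fraction: 0.689
synaptic C1q-NP1 fraction: 0.689
observed median distance: 37 nm
mean shuffled median:     782 nm
```

A handful of planted spots fall too close together or too close to the
field border to be resolved as separate maxima, so 196/200 is the expected
segmentation yield at this density.  The recovered colocalized fraction
(0.689) sits on the planted 0.67 plus a small chance-overlap contribution,
and the observed median minimal distance (37 nm) is far below the shuffled
median (782 nm) — the attraction is real, which the 18-image signed-rank
test would confirm.

The same stages are available from the shell:

```sh
synaptoquant simulate --out scene --seed 1
synaptoquant segment scene --channel c1q --out c1q.csv
synaptoquant coloc scene --spots-a c1q.csv --spots-b np1.csv --out coloc.json
synaptoquant flow --control control.csv --sample sample.csv --out flow.json
synaptoquant deconv --table densitometry.csv --protein np1 --out levels.csv
synaptoquant run-all --config run.yaml
```

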