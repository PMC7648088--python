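# fibroswarm

Quantification of collective fibroblast migration — the image- and
track-analysis toolkit behind the observation that scar-forming fascia
fibroblasts migrate as directed, adherent "swarms" towards a wound
centre, while non-scarring (e.g. oral-mucosa) fibroblasts move as an
uncoordinated random walk at roughly half the speed.

The package is aimed at researchers analysing time-lapse fluorescence
microscopy of migrating cell populations and trichrome-stained
histology.  It bundles:

* **`fibroswarm.synth`** — an agent-based swarm simulator (a minimal
  Vicsek model with centripetal attraction), a fluorescence-movie
  renderer, flow-advected speckle pairs, binary fractal patterns and
  trichrome-like histology fixtures — all with exact ground truth.
* **`fibroswarm.piv`** — iterative cross-correlation particle image
  velocimetry (64/32/16 px window cascade, 3-point Gaussian sub-pixel
  peak fit, window offsetting) with normalized-median-test vector
  validation (noise 0.2, threshold 5).
* **`fibroswarm.tracks`** — detection linking, 3D step kinematics,
  landmark displacement, time-coded track overlays, and the
  **movement-similarity score**: for each cell and frame interval, the
  mean 3D angle between its displacement vector and those of its
  Delaunay-triangulation neighbours,

  $$S = \operatorname{mean}_{i,t}\ \operatorname{mean}_{j \in N_\Delta(i,t)} \angle\big(\mathbf{v}_i(t), \mathbf{v}_j(t)\big),$$

  which is 0° for perfectly uniform migration and 90° in expectation for
  isotropic random motion (the cosine of the angle between independent
  isotropic vectors is uniform on [−1, 1]).
* **`fibroswarm.quant`** — enrichment index
  `MFI_G / (MFI_G + MFI_R)`, box-counting fractal dimension and
  lacunarity, CMYK-based trichrome quantification (nuclei counting and
  collagen/scar area), structure-tensor orientation fields, and
  leading-front contour extraction with gradient-line trajectory
  prediction.
* **`fibroswarm.io` / `fibroswarm.pipeline` / `fibroswarm.cli`** —
  CSV/TIFF readers and writers, provenance-stamped multi-stage runs, and
  a thin `fibroswarm` command-line interface.

## Worked example

```python
import fibroswarm as fs
from fibroswarm.synth import mean_distance_to_centre

swarm_cfg = fs.SwarmConfig(mode="swarm", n_cells=200, n_frames=60, speed=2.0,
                           attraction_weight=1.0, alignment_weight=1.0,
                           noise_weight=0.3, seed=0)
random_cfg = fs.SwarmConfig(mode="random", n_cells=200, n_frames=60, speed=2.0, seed=0)

for name, cfg in [("swarm", swarm_cfg), ("random", random_cfg)]:
    tracks = fs.simulate_tracks(cfg)
    score = fs.movement_similarity(tracks).global_score
    d = mean_distance_to_centre(tracks)
    print(name, round(score, 2), round(d.iloc[0], 1), "->", round(d.iloc[-1], 1))
```

prints

```
swarm 16.4 137.6 -> 31.0
random 89.91 137.6 -> 139.3
```

i.e. with adhesion/alignment couplings on, cells move in near-parallel
paths (similarity 16° ≪ 90°) and collapse towards the arena centre
(mean distance 138 → 31 px); with couplings off the same cells at the
same speed score ≈ 90° and do not drift.  The `examples/` directory has
one short script per capability (`simulate_and_score.py`,
`piv_translation.py`, `fractal_dimension.py`,
`trichrome_quantification.py`, `front_and_orientation.py`), each
printing the numbers it computes and what they mean.

From the shell:

```bash
fibroswarm simulate --out tracks.csv --mode swarm --n-cells 200 --seed 0
fibroswarm similarity tracks.csv --out scores.csv
fibroswarm piv movie.tif --out vectors.csv --windows 64,32,16 --noise 0.2 --threshold 5
```

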