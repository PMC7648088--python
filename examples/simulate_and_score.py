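"""Simulate swarming vs. random fibroblast migration and score their order.

Two simulations share speed, density and duration; only the couplings
differ.  The movement-similarity score is the mean 3D angle between the
per-frame displacement vectors of Delaunay-neighbouring cells: near 0
degrees for collectively aligned ("swarming") migration, near 90 degrees
for isotropic random motion.
"""

import fibroswarm as fs
from fibroswarm.synth import mean_distance_to_centre

swarm_cfg = fs.SwarmConfig(
    mode="swarm", n_cells=200, n_frames=60, speed=2.0,
    attraction_weight=1.0, alignment_weight=1.0, noise_weight=0.3, seed=0,
)
random_cfg = fs.SwarmConfig(mode="random", n_cells=200, n_frames=60, speed=2.0, seed=0)

for name, cfg in [("swarm", swarm_cfg), ("random", random_cfg)]:
    tracks = fs.simulate_tracks(cfg)
    score = fs.movement_similarity(tracks).global_score
    d = mean_distance_to_centre(tracks)
    kin, _ = fs.step_kinematics(tracks, dt=cfg.dt)
    print(
        f"{name:>6}: similarity {score:6.2f} deg | "
        f"mean distance-to-centre {d.iloc[0]:6.1f} -> {d.iloc[-1]:6.1f} px | "
        f"mean velocity {kin['velocity'].mean():.3f} px/min"
    )

print(
    "\nA low similarity score with shrinking distance-to-centre is the "
    "signature of centre-directed collective migration; ~90 deg with a "
    "stable distance is an uncoordinated random walk."
)
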