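"""Simulate the synthetic colony: grid, truth tracks, detections, calibration.

Writes receivers/truth/detections/calibration/dyad-metadata CSVs to
scratch/analysis/ for the downstream drivers.
"""

import numpy as np

from common import CONFIG, SCRATCH, ensure_dirs
from pairtrack import io, synthetic
from pairtrack.pipeline import simulate_scene

ensure_dirs()
seeds = np.random.SeedSequence(CONFIG.seed).spawn(4)
rng_move = np.random.default_rng(seeds[0])
rng_obs = np.random.default_rng(seeds[1])

receivers = synthetic.make_grid(
    CONFIG.grid.extent_x, CONFIG.grid.extent_y, CONFIG.grid.spacing, CONFIG.grid.layout
)
truth, dyad_meta = simulate_scene(CONFIG, rng_move)
obs = CONFIG.observation.to_model()
calib = synthetic.simulate_calibration(
    obs=obs, reps_per_distance=CONFIG.observation.calib_reps_per_distance, seed=rng_obs
)
detections = synthetic.simulate_detections(truth, receivers, obs, rng_obs)

io.write_table(receivers, SCRATCH / "receivers.csv")
io.write_table(truth, SCRATCH / "truth.csv")
io.write_table(detections, SCRATCH / "detections.csv")
io.write_table(calib, SCRATCH / "calibration.csv")
io.write_table(dyad_meta, SCRATCH / "dyads_meta.csv")

pairs = (dyad_meta["relationship"] == "partner").sum()
print(f"receivers: {len(receivers)} on a {CONFIG.grid.spacing:.0f} m {CONFIG.grid.layout} grid")
print(f"birds: {truth['tag_id'].nunique()} ({pairs} pairs across {CONFIG.movement.n_sites} sites)")
print(f"detections: {len(detections)} over {CONFIG.movement.duration:.0f} s "
      f"({CONFIG.observation.rss_noise_sd:.0f} dB RSS noise)")
print(f"dyads: {len(dyad_meta)} ({pairs} partner, {len(dyad_meta) - pairs} neighbour)")
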