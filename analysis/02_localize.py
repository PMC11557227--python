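"""Fit the calibration, localize every (tag, interval), assess accuracy.

Reads the simulated scene from scratch/analysis/, writes the fix table
there and the accuracy summary to results/analysis/.
"""

import json

import numpy as np
import pandas as pd

from common import CONFIG, RESULTS, SCRATCH, ensure_dirs
from pairtrack import io
from pairtrack.localization import LocalizationConfig, assess_accuracy, fit_calibration, localize_all

ensure_dirs()
receivers = io.read_receivers(SCRATCH / "receivers.csv")
detections = io.read_detections(SCRATCH / "detections.csv")
calib = io.read_calibration(SCRATCH / "calibration.csv")
truth = pd.read_csv(SCRATCH / "truth.csv")

model = fit_calibration(calib)
print(f"calibration: log10(d) = {model.b0:.5f} + {model.b1:.5f}*RSS "
      f"(resid SD {model.resid_sd:.3f} log10-m, ceiling {model.d_max:.0f} m)")

seed_loc = int(np.random.SeedSequence(CONFIG.seed).spawn(4)[2].generate_state(1)[0] % (2**31))
lc = CONFIG.localization
config = LocalizationConfig(window=lc.window, lag=lc.lag, retain_radius=lc.retain_radius,
                            min_receivers=lc.min_receivers, n_reps=lc.n_reps,
                            perturb=lc.perturb, seed=seed_loc)
locs = localize_all(detections, receivers, model, config)
io.write_table(locs, SCRATCH / "localizations.csv")

acc = assess_accuracy(locs, truth)
with open(RESULTS / "accuracy.json", "w") as fh:
    json.dump(acc, fh, indent=2)

n_birds = detections["tag_id"].nunique()
print(f"localizations: {len(locs)} fixes for {n_birds} birds "
      f"(possible intervals/bird: {CONFIG.movement.duration / lc.window:.0f})")
print(f"accuracy vs truth: median {acc['median']:.1f} m, 90% < {acc['q90']:.1f} m, "
      f"95% < {acc['q95']:.1f} m")
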