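# pairtrack

Signal-strength localization and pair-cohesion analysis for automated
radio-telemetry grids.

Dense grids of fixed radio receivers ("nodes") can track dozens of
small tagged animals simultaneously: every few seconds each tag's
beacon is heard by nearby receivers, and the received signal strength
(RSS) of those detections encodes distance. `pairtrack` turns such
detection streams into position estimates with uncertainty, and then
into the movement-ecology quantities used to study how much two
animals — e.g. the members of a mated songbird pair versus two
neighbours from the same colony — share space and move together.

The chain, each step a tested library function:

1. **Calibration** — OLS fit of `log10(distance) = b0 + b1·RSS` to
   known-distance observations, with distance predictions truncated at
   the calibrated ceiling (default 150 m) and delta-method standard
   errors.
2. **Localization** — RSS averaged in tumbling 15 s windows (5 s lag);
   receivers within 200 m of the strongest retained; nonlinear
   least-squares multilateration over ≥3 receivers, repeated for 100
   distance-resampled replicates; the replicate cloud gives the
   position and its 2-sigma error ellipse.
3. **Trajectories** — 2.5 km median-distance outlier filter;
   simultaneous-fix pairing; dyadic separation summaries.
4. **Space use** — gridded kernel utilization distributions (UDs) with
   error-inflated bandwidth; 95% home-range areas; overlap via the
   Bhattacharyya coefficient `BC = Σ√(pᵢqᵢ)`; per-track
   Ornstein–Uhlenbeck movement fits; and the **proximity ratio** —
   observed mean separation divided by the mean separation of paths
   re-simulated under independent movement (<1 attraction, ≈1
   independence, >1 avoidance).
5. **Comparison** — weighted within-site permutation tests of
   partner-vs-neighbour differences.

A synthetic-data module simulates the whole observation process —
receiver grids, OU movement with tunable pair coupling, RSS noise,
detection dropout, calibration exercises — with known ground truth, so
every stage is validated by parameter recovery. See
[docs/methods.md](docs/methods.md) for the models and their
assumptions.

## Worked example

Simulate a coupled pair on a 150 m triangular grid, localize it, and
check accuracy against the known truth:

```python
import pandas as pd
import pairtrack as pt

grid = pt.make_grid(1224, 1224, spacing=150, layout="triangular")
pair = pt.MovementParams(center_x=612, center_y=612,
                         sigma_pos=150, tau=240, sigma_sep=50)
a, b = pt.simulate_pair(pair, duration=2400, dt=5, seed=1)
obs = pt.ObservationModel(rss_noise_sd=5.0)          # beacons every 5 s
detections = pt.simulate_detections([a, b], grid, obs, seed=2)

calib = pt.simulate_calibration(obs=pt.ObservationModel(rss_noise_sd=0.0), seed=0)
model = pt.fit_calibration(calib)
print(f"log10(d) = {model.b0:.5f} + {model.b1:.5f}*RSS, ceiling {model.d_max:.0f} m")

locs = pt.localize_all(detections, grid, model, pt.LocalizationConfig(seed=3))
acc = pt.assess_accuracy(locs, pd.concat([a, b]))
print(f"{len(locs)} fixes, median error {acc['median']:.1f} m")
```

```
log10(d) = -1.27009 + -0.03302*RSS, ceiling 150 m
322 fixes, median error 33.0 m
```

The fitted calibration reproduces the generating coefficients exactly
(noiseless draws), and the 33 m median position error at 5 dB RSS
noise is the accuracy scale typical of 150 m node grids.

The full synthetic study — two colony sites, three pairs each —
runs as numbered drivers (`analysis/01_simulate.py` …
`05_compare.py`), or in one call:

```bash
pairtrack run-all --seed 42 --outdir results/run
```

which prints, for that seed:

```
median BC: partner 0.980 vs neighbour 0.871
median proximity ratio: partner 0.325 vs neighbour 0.873
```

i.e. partners use nearly identical home ranges and stay far closer
than independent movement would predict, while same-site neighbours
show high overlap but much weaker attraction — the qualitative
signature of strong pair cohesion against a social, non-territorial
background. Dyad tables (`dyads.csv`, `proximity.csv`,
`bc_matrix.csv`) and permutation-test results land in the output
directory.

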