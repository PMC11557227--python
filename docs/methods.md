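# Methods

`pairtrack` implements an automated radio-telemetry analysis chain for
dense receiver ("node") grids: signal-strength localization of tagged
animals, trajectory cleaning, home-range estimation and overlap, and
dyadic proximity analysis against a simulated independent-movement
null. It ships with a synthetic-data generator so every stage can be
validated against known ground truth.

## Localization model

**RSS–distance calibration.** Received signal strength (RSS, dB) is
related to distance by the log-linear model

    log10(d) = b0 + b1 · RSS,      b1 < 0.

The model is fitted by ordinary least squares of `log10(distance)` on
RSS from calibration observations (tags held at fixed distances from
receivers; the default protocol uses 1, 2, 5, 10, 15, 25, 50, 75, 100
and 150 m with 24 draws per distance). The default coefficients,
`b0 = −1.27009` and `b1 = −0.03302`, are the published field
calibration for this tag/receiver system. Distance predictions beyond
the largest calibrated distance (`d_max`, default 150 m) are truncated
to that ceiling, since the curve is unconstrained beyond it. The
standard error of a distance estimate comes from the delta method on
the log10 scale, `se(d) ≈ d · ln(10) · resid_sd`, evaluated on the
untruncated prediction and carried unchanged through truncation (the
uncertainty of a truncated distance is not reduced by truncating it).

**Windowing.** RSS is averaged per (tag, receiver) in tumbling 15 s
windows shifted 5 s early, i.e. interval *k* covers `[15k − 5, 15k + 10)`.
Window alignment is a convention, not physics; it is a config constant
(`window`, `lag`) and the tests pin the chosen convention.

**Receiver selection.** Within each interval, only receivers within
200 m of the receiver with the strongest averaged RSS are retained
(ties broken deterministically by receiver id). This suppresses
far-field receivers whose distance estimates are dominated by the
truncation ceiling.

**Multilateration.** With at least three retained receivers, the
position minimizes `Σᵢ (‖p − rᵢ‖ − dᵢ)²`. To propagate distance
uncertainty, 100 replicate solutions are computed, each perturbing
every distance by `Normal(0, se)` (a `uniform` switch is provided),
floored at 0.1 m. The solver is a damped Gauss–Newton iteration
vectorized across all replicates, started from the
inverse-distance-weighted receiver centroid; replicates landing more
than two hull-diagonals outside the receiver bounding box are treated
as non-converged, and an interval with more than half of its
replicates failing yields no fix. The replicate cloud's mean is the
reported position; its sample-covariance eigendecomposition gives the
2-sigma error ellipse (axes `2√λ`, containing `1 − e⁻² ≈ 0.8647` of a
bivariate normal's mass). Tests cross-check the solver against
`scipy.optimize.least_squares` and a dense grid-search oracle.

## Trajectory cleaning and dyad summaries

Fixes farther than 2.5 km from an individual's median point
(component-wise medians) are discarded. "Simultaneous" fixes of two
individuals are fixes sharing a localization interval (a tolerance in
intervals is available for sensitivity checks). Dyad summaries report
the median separation across simultaneous fixes, the fraction of fixes
that are simultaneous (denominator: the mean of the two individuals'
fix counts), and the median time from each fix to the partner's
nearest fix. Note that the observed separation of a perfectly glued
pair is *not* zero: it confounds true separation with two independent
localization errors, so it floors at roughly √2 times the single-fix
error scale.

## Space use

**Utilization distributions.** The UD is a gridded Gaussian kernel
density of the fix positions (histogram convolved with a Gaussian,
mass renormalized to exactly 1). The automatic bandwidth is
Silverman's rule per axis for two dimensions (`σ̂ · n^(−1/6)`) inflated
in quadrature by the mean fix-error scale (RMS of the error-ellipse
semi-axes / 2), so noisier localizations widen the estimated range.
The grid pads three bandwidths beyond the fix bounding box; default
cell size 25 m (desk scale; any cell well below the bandwidth gives
equivalent results since binning adds only `cell²/12` to the effective
kernel variance). This is deliberately a plain KDE with
uncertainty-inflated bandwidth — not autocorrelated KDE with
continuous-time model selection. That simplification biases absolute
home-range areas and overlap values (autocorrelated fixes carry less
information than independent ones), which is why absolute overlap
values are not comparison targets here; partner/neighbour *orderings*
are insensitive to it.

**Home range and overlap.** The 95% home range is the smallest set of
grid cells holding ≥95% of UD mass (level accepted in (0, 1]). Overlap
is the Bhattacharyya coefficient `BC = Σ √(pᵢqᵢ)` after re-binning
both UDs onto a common grid at the coarser cell size with
mass-preserving aggregation (each cell's mass moves whole to the
target cell containing its centre — bilinear schemes would break
`Σ = 1` exactness).

**Movement fit.** Each track is summarized by a stationary
Ornstein–Uhlenbeck (OU) model: centre = mean position, `sigma_pos` =
pooled per-axis SD, and timescale `tau` from a log-linear fit to the
positional autocorrelation over lags with ACF > 0.2, weighted by the
ACF value (near-floor lags are the noisiest on the log scale). Fixes
are treated as evenly spaced at the median fix interval; a
non-positive lag-1 ACF floors `tau` at that interval with a warning.
Recovery tests show `sigma_pos` within ~10% and `tau` within ~25% at
5000 fixes — `tau` is intrinsically noisy because the effective sample
size is the track length divided by `2·tau`.

**Proximity ratio.** The observed mean separation across simultaneous
fixes is divided by the mean separation of paths re-simulated under
independence: for each of `n_sims` replicates, each individual is
simulated as an independent stationary OU process from its own fitted
model at the same fix times. The CI divides the observed value by the
null's 97.5%/2.5% quantiles, so the interval excludes 1 exactly when
the observed separation falls outside the null band. The null mean
separation depends only on the fitted centres and SDs (for independent
stationary processes the expected instantaneous separation is a
marginal property), which makes the ratio robust to `tau` estimation
error; `tau` affects only the width of the null band. The null
simulates unconditioned stationary paths rather than paths conditioned
on the observed fixes; this affects absolute ratios slightly but not
partner/neighbour orderings.

## Partner-vs-neighbour inference

Group contrasts (overlap, proximity ratio, median separation) use a
weighted-mean-difference statistic (weights: time simultaneously
tracked) with a permutation null that shuffles relationship labels
*within sub-colony site*, p-values with the add-one correction
`(1 + #{|null| ≥ |obs|}) / (n_perm + 1)`. This replaces mixed-model
likelihood-ratio tests: restricted permutation conditions on
site-level structure without a parametric model, though no permutation
scheme exactly reproduces crossed individual/partner random effects —
the scheme conditions on site only, stated openly. Type-I error is
verified by simulation (rejection rate at α = 0.05 within [0.02, 0.09]
over 200 null replicates).

## Synthetic scenes

The generator emulates: a ~1.5 km² triangular receiver grid at 150 m
spacing (row pitch `150·√3/2 ≈ 129.9` m, 85 receivers at the default
extent); tags beaconing every 5 s; RSS generated by inverting the
calibration curve plus Gaussian noise; and a hard 400 m detection
radius. Movement is exact-transition OU (AR(1) with `φ = e^(−Δt/τ)`),
stationary from the first sample at any step size. A pair is a shared
OU path ± half an independent OU separation vector (SD `sigma_sep`),
so the stationary separation distribution is known in closed form.

Defaults were chosen once to match the field system's reported scales:
`tau = 240 s`, per-axis marginal SD ≈ 152 m (giving a 95% Gaussian
home-range area ≈ 0.44 km²), `sigma_sep = 50 m` (true median pair
separation ≈ 56 m), RSS noise 5 dB (not a published value — the field
noise magnitude is unreported — exposed as `rss_noise_sd`). With these
settings the pipeline's realized median localization error is ~35 m,
matching the accuracy reported for field calibrations of such grids.

The end-to-end scene adds a third movement level: a site-shared OU
drift (`sigma_site = 90 m`) under the pair-shared path
(`sigma_pair = 120 m`), so birds of one site co-visit areas and
neighbour dyads show mild attraction (expected ratio ≈ 0.8) while
partners show strong attraction (ratio ≈ 0.3 after localization
noise). The default study runs 2 sites × 3 pairs for 2400 s at
`dt = 5 s` (160 intervals per bird) — sizes chosen so the full study
and its replicate tests run comfortably on a single CPU.

What the generator does **not** emulate: detection-probability decay
(dropout is a hard radius), solar duty-cycling and antenna failures,
topography/vegetation effects on RSS, multipath beyond what the
windowed averaging removes, non-stationary movement (foraging trips,
nest attendance bouts), and geographic coordinates (everything is
local planar metres). Passing tests therefore demonstrate correctness
of the estimators under a stationary, well-behaved observation model —
not robustness to every field pathology.

## Numerical choices and degenerate inputs

- Distances are floored at 0.1 m before `log10`; perturbed replicate
  distances at 0.1 m.
- Gauss–Newton damping: Levenberg parameter per replicate, ×0.3 on
  accepted steps, ×5 on rejected; iteration stops when all proposed
  steps fall below 1e-8 m.
- Strongest-receiver ties break lexicographically by receiver id;
  equal-mass UD cells rank arbitrarily but deterministically.
- Degenerate UD inputs (all fixes identical) fall back to a cell-size
  bandwidth with a warning; constant tracks are rejected by the
  movement fit.
- All stochastic functions take explicit seeds or Generators; the
  pipeline derives per-stage streams from one root seed via
  `SeedSequence.spawn`, and CSV floats are written at fixed precision
  so a fixed config + seed reproduces outputs byte-for-byte.

## Known limitations

- Plain KDE UDs understate the range of strongly autocorrelated, short
  tracks; absolute BC and area values should be read comparatively.
- The `tau` estimator assumes near-regular sampling; long detection
  gaps bias it.
- The proximity CI inherits Monte-Carlo noise from `n_sims`
  (default 50–100); CIs near 1 should be interpreted with that in
  mind.
- The outlier filter is single-pass; it is idempotent for realistic
  clouds but not for adversarial configurations poised exactly at the
  threshold.
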