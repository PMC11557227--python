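"""Utilization distributions, home-range overlap and proximity ratios.

The utilization distribution (UD) is a gridded Gaussian kernel density
of an individual's fixes, with the bandwidth inflated by the mean
localization-error ellipse scale so positional uncertainty widens the
estimated range.  Overlap between two UDs is the Bhattacharyya
coefficient ``sum sqrt(p*q)``.  Spatio-temporal attraction is measured
by the proximity ratio: the observed mean separation of simultaneous
fixes divided by the mean separation of paths re-simulated from each
individual's fitted movement model under independence.  Ratios below 1
indicate attraction, about 1 independence, above 1 avoidance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import ou_paths
from .trajectories import pair_fixes

__all__ = [
    "UtilizationDistribution",
    "FittedMovement",
    "ProximityResult",
    "estimate_ud",
    "home_range_area",
    "bhattacharyya",
    "to_common_grid",
    "fit_movement",
    "proximity_ratio",
]

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class UtilizationDistribution:
    """Normalized probability mass on a regular grid.

    ``mass[iy, ix]`` is the mass of the cell whose lower-left corner is
    ``(origin_x + ix*cell, origin_y + iy*cell)``.
    """

    origin_x: float
    origin_y: float
    cell: float
    mass: np.ndarray

    def __post_init__(self) -> None:
        if not (self.cell > 0):
            raise ValueError("cell must be > 0")
        if self.mass.ndim != 2 or np.any(self.mass < 0):
            raise ValueError("mass must be a non-negative 2-D array")
        if abs(float(self.mass.sum()) - 1.0) > _MASS_TOL:
            raise ValueError("mass must sum to 1")

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.mass.shape[1]) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.mass.shape[0]) + 0.5) * self.cell


@dataclass(frozen=True)
class FittedMovement:
    """OU movement model fitted to a track (centre, positional SD, timescale)."""

    center_x: float
    center_y: float
    sigma_pos: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.sigma_pos > 0) or not (self.tau > 0):
            raise ValueError("sigma_pos and tau must be > 0")


@dataclass(frozen=True)
class ProximityResult:
    ratio: float
    ci_low: float
    ci_high: float
    n_sims: int


def _silverman_bandwidth(values: np.ndarray) -> float:
    # multivariate Silverman for d=2: h = sigma * n^(-1/6)
    return float(np.std(values, ddof=1) * len(values) ** (-1.0 / 6.0))


def estimate_ud(
    track: pd.DataFrame,
    cell: float = 15.0,
    bandwidth: float | str = "auto",
    min_fixes: int = 10,
) -> UtilizationDistribution:
    """Gridded Gaussian-kernel UD of a track's fixes.

    ``bandwidth="auto"`` uses Silverman's rule per axis inflated (in
    quadrature) by the mean localization-error scale of the fixes, taken
    from their error-ellipse axes when present.  The grid pads three
    bandwidths beyond the fix bounding box; mass is normalized to 1.
    """
    if len(track) < min_fixes:
        raise ValueError(f"need >= {min_fixes} fixes, got {len(track)}")
    x = track["x"].to_numpy(dtype=float)
    y = track["y"].to_numpy(dtype=float)

    if bandwidth == "auto":
        hx = _silverman_bandwidth(x)
        hy = _silverman_bandwidth(y)
        if hx <= 0 or hy <= 0:
            warnings.warn("degenerate track: falling back to cell-size bandwidth")
            hx = hy = cell
        if "ell_a" in track.columns:
            # 1-sigma positional scale of a fix: RMS of the ellipse semi-axes / 2
            err = np.sqrt(((track["ell_a"] / 2.0) ** 2 + (track["ell_b"] / 2.0) ** 2) / 2.0)
            s = float(np.nanmean(err))
            hx = float(np.hypot(hx, s))
            hy = float(np.hypot(hy, s))
    else:
        hx = hy = float(bandwidth)
        if hx <= 0:
            raise ValueError("bandwidth must be > 0")

    pad_x, pad_y = 3.0 * hx, 3.0 * hy
    ox = np.floor((x.min() - pad_x) / cell) * cell
    oy = np.floor((y.min() - pad_y) / cell) * cell
    nx = int(np.ceil((x.max() + pad_x - ox) / cell)) + 1
    ny = int(np.ceil((y.max() + pad_y - oy) / cell)) + 1

    ix = np.clip(((x - ox) / cell).astype(int), 0, nx - 1)
    iy = np.clip(((y - oy) / cell).astype(int), 0, ny - 1)
    hist = np.zeros((ny, nx))
    np.add.at(hist, (iy, ix), 1.0)

    mass = ndimage.gaussian_filter(hist, sigma=(hy / cell, hx / cell), mode="constant")
    total = mass.sum()
    if total <= 0:
        raise ValueError("empty density")
    return UtilizationDistribution(origin_x=ox, origin_y=oy, cell=cell, mass=mass / total)


def home_range_area(ud: UtilizationDistribution, level: float = 0.95) -> float:
    """Area (km^2) of the smallest cell set holding >= ``level`` of the mass."""
    if not (0.0 < level <= 1.0):
        raise ValueError(f"level must be in (0, 1], got {level}")
    flat = np.sort(ud.mass.ravel())[::-1]
    csum = np.cumsum(flat)
    n_cells = int(np.searchsorted(csum, level - 1e-12) + 1)
    n_cells = min(n_cells, flat.size)
    return n_cells * ud.cell**2 / 1e6


def _grids_match(a: UtilizationDistribution, b: UtilizationDistribution) -> bool:
    tol = 1e-6 * a.cell
    return (
        a.mass.shape == b.mass.shape
        and abs(a.cell - b.cell) <= tol
        and abs(a.origin_x - b.origin_x) <= tol
        and abs(a.origin_y - b.origin_y) <= tol
    )


def _rebin(
    ud: UtilizationDistribution, ox: float, oy: float, cell: float, nx: int, ny: int
) -> UtilizationDistribution:
    # mass-preserving: each source cell's mass goes to the target cell
    # containing its centre
    xc, yc = np.meshgrid(ud.x_centers, ud.y_centers)
    ix = np.clip(((xc - ox) / cell).astype(int), 0, nx - 1)
    iy = np.clip(((yc - oy) / cell).astype(int), 0, ny - 1)
    mass = np.zeros((ny, nx))
    np.add.at(mass, (iy.ravel(), ix.ravel()), ud.mass.ravel())
    return UtilizationDistribution(origin_x=ox, origin_y=oy, cell=cell, mass=mass)


def to_common_grid(
    a: UtilizationDistribution, b: UtilizationDistribution
) -> tuple[UtilizationDistribution, UtilizationDistribution]:
    """Re-bin two UDs onto one grid at the coarser of the two cell sizes.

    Aggregation is conservative (each cell's mass moves whole), so both
    outputs still sum to exactly 1.
    """
    cell = max(a.cell, b.cell)
    ox = np.floor(min(a.origin_x, b.origin_x) / cell) * cell
    oy = np.floor(min(a.origin_y, b.origin_y) / cell) * cell
    x_hi = max(a.origin_x + a.cell * a.mass.shape[1], b.origin_x + b.cell * b.mass.shape[1])
    y_hi = max(a.origin_y + a.cell * a.mass.shape[0], b.origin_y + b.cell * b.mass.shape[0])
    nx = int(np.ceil((x_hi - ox) / cell))
    ny = int(np.ceil((y_hi - oy) / cell))
    return _rebin(a, ox, oy, cell, nx, ny), _rebin(b, ox, oy, cell, nx, ny)


def bhattacharyya(a: UtilizationDistribution, b: UtilizationDistribution) -> float:
    """Bhattacharyya coefficient ``sum sqrt(p*q)`` between two UDs.

    Both UDs must live on the same grid; use :func:`to_common_grid`
    first when they do not.
    """
    if not _grids_match(a, b):
        raise ValueError("UD grids differ; resample with to_common_grid first")
    return float(np.sqrt(a.mass * b.mass).sum())


def fit_movement(track: pd.DataFrame, min_fixes: int = 50, acf_floor: float = 0.2) -> FittedMovement:
    """Fit a stationary OU model to a fix series.

    Centre = mean position; ``sigma_pos`` = pooled per-axis SD; ``tau``
    from a log-linear fit to the positional autocorrelation over lags
    where the ACF exceeds ``acf_floor`` (fixes are treated as evenly
    spaced at the median fix interval).  A non-positive lag-1 ACF floors
    ``tau`` at the sampling interval with a warning.
    """
    from statsmodels.tsa.stattools import acf as sm_acf

    if len(track) < min_fixes:
        raise ValueError(f"need >= {min_fixes} fixes, got {len(track)}")
    x = track["x"].to_numpy(dtype=float)
    y = track["y"].to_numpy(dtype=float)
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 and sy == 0:
        raise ValueError("constant track: movement model undefined")
    sigma = float(np.sqrt((sx**2 + sy**2) / 2.0))

    dt = float(np.median(np.diff(np.sort(track["t_mid"].to_numpy(dtype=float)))))
    if not (dt > 0):
        dt = 1.0
    nlags = min(len(track) // 3, 200)
    rho = (sm_acf(x, nlags=nlags, fft=True) + sm_acf(y, nlags=nlags, fft=True)) / 2.0

    if rho[1] <= 0:
        warnings.warn("non-positive lag-1 autocorrelation; tau floored at the fix interval")
        tau = dt
    else:
        lags = np.arange(1, nlags + 1)
        use = rho[1:] > acf_floor
        # stop at the first lag below the floor to keep the fit in the
        # exponential-decay regime
        if use.any():
            first_bad = np.argmax(~use) if (~use).any() else use.size
            use[first_bad:] = False
        if use.sum() >= 2:
            # weight by rho: var(log rho_hat) ~ var(rho_hat)/rho^2, so the
            # near-floor lags are the noisiest on the log scale
            slope = np.polyfit(
                lags[use] * dt, np.log(rho[1:][use]), 1, w=rho[1:][use]
            )[0]
            tau = -1.0 / slope if slope < 0 else dt
        else:
            tau = -dt / np.log(rho[1])
    return FittedMovement(
        center_x=float(np.mean(x)),
        center_y=float(np.mean(y)),
        sigma_pos=max(sigma, 1e-9),
        tau=max(float(tau), 1e-9),
    )


def proximity_ratio(
    track_a: pd.DataFrame,
    track_b: pd.DataFrame,
    fit_a: FittedMovement,
    fit_b: FittedMovement,
    n_sims: int = 100,
    seed: int | np.random.Generator = 0,
    min_paired: int = 10,
) -> ProximityResult:
    """Observed over expected-under-independence mean separation.

    The observed statistic is the mean separation across simultaneous
    fixes.  The null re-simulates each individual as an independent
    stationary OU process from its fitted model at the same fix times,
    ``n_sims`` times; the ratio divides observed by the null mean, and
    the CI divides observed by the null's 97.5% / 2.5% quantiles (so the
    CI excludes 1 exactly when the observed separation falls outside the
    null band).
    """
    if n_sims < 20:
        raise ValueError("n_sims must be >= 20 for stable quantiles")
    paired = pair_fixes(track_a, track_b)
    if len(paired) < min_paired:
        raise ValueError(f"need >= {min_paired} paired fixes, got {len(paired)}")
    observed = float(paired["separation"].mean())
    times = np.sort(np.unique(paired["t_mid"].to_numpy(dtype=float)))

    rng = np.random.default_rng(seed)
    ax = ou_paths(times, fit_a.tau, fit_a.sigma_pos, rng, n_paths=n_sims) + fit_a.center_x
    ay = ou_paths(times, fit_a.tau, fit_a.sigma_pos, rng, n_paths=n_sims) + fit_a.center_y
    bx = ou_paths(times, fit_b.tau, fit_b.sigma_pos, rng, n_paths=n_sims) + fit_b.center_x
    by = ou_paths(times, fit_b.tau, fit_b.sigma_pos, rng, n_paths=n_sims) + fit_b.center_y
    sim_means = np.hypot(ax - bx, ay - by).mean(axis=1)

    ratio = observed / float(sim_means.mean())
    ci_low = observed / float(np.quantile(sim_means, 0.975))
    ci_high = observed / float(np.quantile(sim_means, 0.025))
    return ProximityResult(ratio=ratio, ci_low=ci_low, ci_high=ci_high, n_sims=n_sims)
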