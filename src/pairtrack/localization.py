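"""RSS-based multilateration of tag positions from a receiver grid.

The localization chain: fit the log-linear RSS--distance calibration;
average RSS within tumbling 15 s windows (shifted 5 s early); keep the
receivers within 200 m of the strongest one; convert averaged RSS to
distance estimates (truncated at the calibration ceiling) with a
delta-method standard error; solve nonlinear least-squares
multilateration for 100 resampled replicates; and summarize the
replicate scatter as a 2-sigma error ellipse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationModel",
    "DEFAULT_CALIBRATION",
    "LocalizationConfig",
    "Localization",
    "fit_calibration",
    "rss_to_distance",
    "window_rss",
    "select_receivers",
    "multilaterate",
    "localize_all",
    "assess_accuracy",
]

logger = logging.getLogger(__name__)

LN10 = np.log(10.0)


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted ``log10(distance) = b0 + b1 * RSS`` relationship.

    ``resid_sd`` is the residual SD on the log10(m) scale and drives the
    delta-method distance s.e.; ``d_max`` is the truncation ceiling --
    the largest distance the calibration covered.
    """

    b0: float
    b1: float
    resid_sd: float = 0.0
    d_max: float = 150.0

    def __post_init__(self) -> None:
        if self.b1 == 0:
            raise ValueError("b1 must be nonzero")
        if not (self.d_max > 0):
            raise ValueError("d_max must be > 0")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be >= 0")


#: The published field calibration for 434 MHz LifeTag beacons on a node grid.
DEFAULT_CALIBRATION = CalibrationModel(b0=-1.27009, b1=-0.03302, resid_sd=0.0, d_max=150.0)


@dataclass(frozen=True)
class LocalizationConfig:
    """Windowing, receiver-selection and resampling settings.

    ``window``/``lag``: RSS is averaged in tumbling ``window``-second bins
    whose boundaries are shifted ``lag`` seconds (negative = earlier), so
    interval ``k`` covers ``[window*k + lag, window*(k+1) + lag)``.
    ``retain_radius``: receivers farther than this from the strongest
    receiver are discarded.  ``n_reps`` replicate solutions are computed
    by perturbing each distance by its s.e. (``perturb`` = ``"normal"``
    or ``"uniform"``).
    """

    window: float = 15.0
    lag: float = -5.0
    retain_radius: float = 200.0
    min_receivers: int = 3
    n_reps: int = 100
    perturb: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.window > 0):
            raise ValueError("window must be > 0")
        if self.min_receivers < 3:
            raise ValueError("min_receivers must be >= 3")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.perturb not in ("normal", "uniform"):
            raise ValueError("perturb must be 'normal' or 'uniform'")

    def interval_index(self, t: np.ndarray | float) -> np.ndarray | int:
        """Tumbling-window index of detection time(s) ``t``."""
        idx = np.floor((np.asarray(t, dtype=float) - self.lag) / self.window)
        return idx.astype(int) if idx.ndim else int(idx)

    def interval_midpoint(self, index: np.ndarray | int) -> np.ndarray | float:
        return np.asarray(index, dtype=float) * self.window + self.window / 2.0 + self.lag


@dataclass(frozen=True)
class Localization:
    """One estimated position with its 2-sigma replicate error ellipse."""

    tag_id: str
    interval_index: int
    t_mid: float
    x: float
    y: float
    ell_a: float
    ell_b: float
    ell_theta: float
    n_receivers: int
    n_reps: int


def fit_calibration(calib: pd.DataFrame) -> CalibrationModel:
    """Ordinary least squares of ``log10(distance_m)`` on ``rss``.

    ``d_max`` is set from the largest calibration distance.  Requires at
    least two distinct distances and non-constant RSS.
    """
    d = calib["distance_m"].to_numpy(dtype=float)
    rss = calib["rss"].to_numpy(dtype=float)
    if np.unique(d).size < 2:
        raise ValueError("need >= 2 distinct calibration distances")
    if np.ptp(rss) == 0:
        raise ValueError("all RSS values identical: singular calibration fit")

    y = np.log10(d)
    b1, b0 = np.polyfit(rss, y, 1)
    resid = y - (b0 + b1 * rss)
    dof = max(resid.size - 2, 1)
    resid_sd = float(np.sqrt(np.sum(resid**2) / dof)) if resid.size > 2 else 0.0
    return CalibrationModel(b0=float(b0), b1=float(b1), resid_sd=resid_sd, d_max=float(d.max()))


def rss_to_distance(
    rss: np.ndarray | float, model: CalibrationModel
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Distance estimate(s) and s.e. for averaged RSS value(s).

    ``d_hat = min(10^(b0 + b1*rss), d_max)``; the s.e. comes from the
    delta method on the log10 scale, ``d * ln(10) * resid_sd``, evaluated
    before truncation and carried unchanged through it.
    """
    arr = np.asarray(rss, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite RSS")
    d_raw = 10.0 ** (model.b0 + model.b1 * arr)
    d_hat = np.minimum(d_raw, model.d_max)
    d_se = d_raw * LN10 * model.resid_sd
    if arr.ndim == 0:
        return float(d_hat), float(d_se)
    return d_hat, d_se


def window_rss(detections: pd.DataFrame, config: LocalizationConfig) -> pd.DataFrame:
    """Average RSS per (tag, interval, receiver) over tumbling windows.

    Returns ``tag_id, interval_index, receiver_id, mean_rss, n_detections``.
    """
    if detections.empty:
        return pd.DataFrame(
            columns=["tag_id", "interval_index", "receiver_id", "mean_rss", "n_detections"]
        )
    df = detections.assign(interval_index=config.interval_index(detections["t"].to_numpy()))
    out = (
        df.groupby(["tag_id", "interval_index", "receiver_id"], sort=True)["rss"]
        .agg(mean_rss="mean", n_detections="size")
        .reset_index()
    )
    out["n_detections"] = out["n_detections"].astype(int)
    return out


def select_receivers(
    interval_rows: pd.DataFrame,
    receivers: pd.DataFrame,
    config: LocalizationConfig,
) -> pd.DataFrame:
    """Keep receivers within ``retain_radius`` of the strongest one.

    ``interval_rows`` must share one (tag, interval).  The anchor is the
    receiver with the largest ``mean_rss`` (ties broken by smallest
    ``receiver_id``) and is always retained.  Output gains ``x, y``.
    """
    merged = interval_rows.merge(
        receivers[["receiver_id", "x", "y"]], on="receiver_id", how="left"
    )
    if merged["x"].isna().any():
        missing = merged.loc[merged["x"].isna(), "receiver_id"].tolist()
        raise ValueError(f"receiver ids absent from receiver table: {missing}")
    anchor = merged.sort_values(
        ["mean_rss", "receiver_id"], ascending=[False, True]
    ).iloc[0]
    dist = np.hypot(merged["x"] - anchor["x"], merged["y"] - anchor["y"])
    return merged.loc[dist <= config.retain_radius].reset_index(drop=True)


def _solve_replicates(
    coords: np.ndarray, dists: np.ndarray, p0: np.ndarray, n_iter: int = 80
) -> np.ndarray:
    """Vectorized damped Gauss-Newton for range-based multilateration.

    Minimizes ``sum_i (||p - r_i|| - d_i)^2`` simultaneously for every
    replicate row of ``dists`` (shape ``(m, k)``); returns ``(m, 2)``
    positions.  Levenberg-style damping with step acceptance keeps the
    iteration stable on this non-convex objective.
    """
    m = dists.shape[0]
    p = np.broadcast_to(p0, (m, 2)).copy()
    lam = np.full(m, 1e-6)

    def residuals(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        dx = pos[:, None, 0] - coords[None, :, 0]
        dy = pos[:, None, 1] - coords[None, :, 1]
        rng_d = np.hypot(dx, dy)
        rng_d = np.maximum(rng_d, 1e-9)
        r = rng_d - dists
        return r, rng_d, (r * r).sum(axis=1)

    r, rng_d, cost = residuals(p)
    for _ in range(n_iter):
        dx = (p[:, None, 0] - coords[None, :, 0]) / rng_d
        dy = (p[:, None, 1] - coords[None, :, 1]) / rng_d
        g0 = (dx * r).sum(axis=1)
        g1 = (dy * r).sum(axis=1)
        a00 = (dx * dx).sum(axis=1) + lam
        a01 = (dx * dy).sum(axis=1)
        a11 = (dy * dy).sum(axis=1) + lam
        det = a00 * a11 - a01 * a01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step0 = (a11 * g0 - a01 * g1) / det
        step1 = (a00 * g1 - a01 * g0) / det
        trial = p - np.stack([step0, step1], axis=1)
        r_t, rng_t, cost_t = residuals(trial)
        ok = cost_t <= cost
        p[ok] = trial[ok]
        r[ok] = r_t[ok]
        rng_d[ok] = rng_t[ok]
        cost[ok] = cost_t[ok]
        lam = np.clip(np.where(ok, lam * 0.3, lam * 5.0), 1e-10, 1e8)
        # all proposed steps negligible -> converged (or fully damped)
        if np.max(np.hypot(step0, step1)) < 1e-8:
            break
    return p


def _ellipse_from_replicates(points: np.ndarray) -> tuple[float, float, float]:
    """2-sigma ellipse (a, b, theta) of a replicate position cloud.

    Axes are ``2 * sqrt(eigenvalue)`` of the sample covariance; theta is
    the orientation of the leading eigenvector in ``[0, pi)``.  Such an
    ellipse contains ``1 - exp(-2)`` of a bivariate normal's mass.
    """
    if points.shape[0] < 2:
        return 0.0, 0.0, 0.0
    cov = np.cov(points.T)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    a = 2.0 * np.sqrt(vals[1])
    b = 2.0 * np.sqrt(vals[0])
    lead = vecs[:, 1]
    theta = float(np.arctan2(lead[1], lead[0])) % np.pi
    return float(a), float(b), theta


def multilaterate(
    estimates: pd.DataFrame,
    config: LocalizationConfig,
    rng: np.random.Generator,
) -> Localization | None:
    """Resampled nonlinear least-squares position from distance estimates.

    ``estimates`` carries one row per retained receiver with columns
    ``receiver_id, x, y, d_hat, d_se`` (``mean_rss`` optional, used for
    the starting point).  Fewer than ``min_receivers`` rows -> ``None``.

    Each of ``n_reps`` replicates perturbs every distance by a draw from
    ``Normal(0, d_se)`` (or ``Uniform(-d_se, d_se)``), floored at 0.1 m,
    and solves ``min_p sum_i (||p - r_i|| - d_i)^2`` from an inverse-
    distance-weighted centroid start.  Replicates landing farther than
    two receiver-hull diagonals outside the hull's bounding box are
    treated as non-converged; if more than half fail, no localization is
    returned.  The replicate cloud's mean is the position and its
    covariance eigendecomposition the 2-sigma error ellipse.
    """
    k = len(estimates)
    if k < config.min_receivers:
        return None
    return _multilaterate_arrays(
        estimates[["x", "y"]].to_numpy(dtype=float),
        estimates["d_hat"].to_numpy(dtype=float),
        estimates["d_se"].to_numpy(dtype=float),
        config,
        rng,
    )


def _multilaterate_arrays(
    coords: np.ndarray,
    d_hat: np.ndarray,
    d_se: np.ndarray,
    config: LocalizationConfig,
    rng: np.random.Generator,
) -> Localization | None:
    k = coords.shape[0]
    if k < config.min_receivers:
        return None
    m = config.n_reps
    if config.perturb == "normal":
        noise = rng.standard_normal((m, k)) * d_se[None, :]
    else:
        noise = rng.uniform(-1.0, 1.0, size=(m, k)) * d_se[None, :]
    dists = np.maximum(d_hat[None, :] + noise, 0.1)

    w = 1.0 / np.maximum(d_hat, 0.1)
    p0 = (coords * w[:, None]).sum(axis=0) / w.sum()

    sols = _solve_replicates(coords, dists, p0)

    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    diag = max(float(np.hypot(*(hi - lo))), 1.0)
    outside = np.maximum(np.maximum(lo - sols, sols - hi), 0.0)
    dist_out = np.hypot(outside[:, 0], outside[:, 1])
    good = np.isfinite(sols).all(axis=1) & (dist_out <= 2.0 * diag)
    if good.sum() <= m / 2.0:
        logger.info("multilateration dropped: %d/%d replicates non-converged", m - good.sum(), m)
        return None

    pts = sols[good]
    mean = pts.mean(axis=0)
    ell_a, ell_b, ell_theta = _ellipse_from_replicates(pts)
    return Localization(
        tag_id="",
        interval_index=0,
        t_mid=np.nan,
        x=float(mean[0]),
        y=float(mean[1]),
        ell_a=ell_a,
        ell_b=ell_b,
        ell_theta=ell_theta,
        n_receivers=int(k),
        n_reps=int(good.sum()),
    )


LOCALIZATION_COLUMNS = [
    "tag_id",
    "interval_index",
    "t_mid",
    "x",
    "y",
    "ell_a",
    "ell_b",
    "ell_theta",
    "n_receivers",
    "n_reps",
]


def localize_all(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    model: CalibrationModel,
    config: LocalizationConfig,
) -> pd.DataFrame:
    """Window, select, and multilaterate every (tag, interval).

    Returns a localization table (one row per successful interval),
    time-sorted within each tag.
    """
    windowed = window_rss(detections, config)
    if windowed.empty:
        return pd.DataFrame(columns=LOCALIZATION_COLUMNS)
    merged = windowed.merge(receivers[["receiver_id", "x", "y"]], on="receiver_id", how="left")
    if merged["x"].isna().any():
        missing = merged.loc[merged["x"].isna(), "receiver_id"].unique().tolist()
        raise ValueError(f"receiver ids absent from receiver table: {missing}")

    tags = merged["tag_id"].to_numpy()
    idxs = merged["interval_index"].to_numpy()
    rids = merged["receiver_id"].to_numpy()
    xs = merged["x"].to_numpy(dtype=float)
    ys = merged["y"].to_numpy(dtype=float)
    d_hat_all, d_se_all = rss_to_distance(merged["mean_rss"].to_numpy(), model)
    rss_all = merged["mean_rss"].to_numpy(dtype=float)

    starts = np.flatnonzero(np.r_[True, (tags[1:] != tags[:-1]) | (idxs[1:] != idxs[:-1])])
    bounds = np.r_[starts, len(merged)]

    rng = np.random.default_rng(config.seed)
    rows: list[Localization] = []
    n_intervals = len(starts)
    for s, e in zip(bounds[:-1], bounds[1:]):
        sub_rss = rss_all[s:e]
        best = np.flatnonzero(sub_rss == sub_rss.max())
        if best.size > 1:  # tie: lexicographically smallest receiver id
            best = best[np.argsort(rids[s:e][best], kind="stable")]
        ai = s + best[0]
        keep = np.hypot(xs[s:e] - xs[ai], ys[s:e] - ys[ai]) <= config.retain_radius
        loc = _multilaterate_arrays(
            np.column_stack([xs[s:e][keep], ys[s:e][keep]]),
            d_hat_all[s:e][keep],
            d_se_all[s:e][keep],
            config,
            rng,
        )
        if loc is None:
            continue
        idx = int(idxs[s])
        rows.append(
            replace(loc, tag_id=tags[s], interval_index=idx, t_mid=float(config.interval_midpoint(idx)))
        )
    logger.info("localized %d/%d (tag, interval) groups", len(rows), n_intervals)
    if not rows:
        return pd.DataFrame(columns=LOCALIZATION_COLUMNS)
    df = pd.DataFrame([r.__dict__ for r in rows])[LOCALIZATION_COLUMNS]
    return df.sort_values(["tag_id", "t_mid"], ignore_index=True)


def assess_accuracy(localizations: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Per-fix Euclidean error of localizations against a truth track.

    The truth track is interpolated linearly at each interval midpoint.
    Returns ``{"n", "median", "q50", "q90", "q95"}`` in metres.
    """
    errors = []
    for tag, grp in localizations.groupby("tag_id"):
        tr = truth.loc[truth["tag_id"] == tag].sort_values("t")
        if tr.empty:
            continue
        tt = tr["t"].to_numpy(dtype=float)
        tx = np.interp(grp["t_mid"], tt, tr["x"].to_numpy(dtype=float))
        ty = np.interp(grp["t_mid"], tt, tr["y"].to_numpy(dtype=float))
        errors.append(np.hypot(grp["x"].to_numpy() - tx, grp["y"].to_numpy() - ty))
    if not errors:
        raise ValueError("no localizations matched the truth table")
    err = np.concatenate(errors)
    return {
        "n": int(err.size),
        "median": float(np.median(err)),
        "q50": float(np.quantile(err, 0.50)),
        "q90": float(np.quantile(err, 0.90)),
        "q95": float(np.quantile(err, 0.95)),
    }
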