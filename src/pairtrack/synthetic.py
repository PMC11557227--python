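"""Synthetic telemetry scenes with known ground truth.

This module generates everything the downstream localization and
space-use pipeline consumes: a receiver grid, movement tracks for
spatially coupled pairs and for independently moving neighbours, beacon
detections with distance-dependent signal strength and noise, and
calibration observations at fixed tag--receiver distances.

Movement is modelled as a stationary Ornstein--Uhlenbeck (OU) process
per axis -- the standard home-range movement model with a positional SD
``sigma_pos`` and an autocorrelation timescale ``tau``.  A mated pair is
simulated as a shared OU path plus/minus half an independent OU
separation vector with SD ``sigma_sep``, so the distribution of the
instantaneous pair separation is known in closed form and parameter
recovery can be tested exactly.

All coordinates are local planar metres; all stochastic operations take
an explicit seed (or :class:`numpy.random.Generator`) -- there is no
hidden global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CALIBRATION_DISTANCES_M",
    "MovementParams",
    "ObservationModel",
    "make_grid",
    "ou_paths",
    "simulate_pair",
    "simulate_independent",
    "simulate_detections",
    "simulate_calibration",
]

#: Distances (m) at which field calibration tags are held from receivers.
CALIBRATION_DISTANCES_M = (1.0, 2.0, 5.0, 10.0, 15.0, 25.0, 50.0, 75.0, 100.0, 150.0)

TRACK_COLUMNS = ["tag_id", "t", "x", "y"]
DETECTION_COLUMNS = ["tag_id", "receiver_id", "t", "rss"]

# Distances are floored here before taking log10, so RSS stays finite
# when a tag sits on top of a receiver.
MIN_DISTANCE_M = 0.1


@dataclass(frozen=True)
class MovementParams:
    """Parameters of the OU movement model for one pair (or individual).

    Attributes
    ----------
    center_x, center_y : float
        Home-range centre in metres.
    sigma_pos : float
        Stationary positional SD of the shared path, per axis (m).
    tau : float
        OU autocorrelation timescale (s).
    sigma_sep : float
        Stationary SD per axis of the pair-separation vector (m).
        ``0`` means a perfectly glued pair.
    """

    center_x: float = 0.0
    center_y: float = 0.0
    sigma_pos: float = 150.0
    tau: float = 240.0
    sigma_sep: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.center_x, self.center_y]).all():
            raise ValueError("centre coordinates must be finite")
        if not (self.sigma_pos > 0):
            raise ValueError(f"sigma_pos must be > 0, got {self.sigma_pos}")
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not (self.sigma_sep >= 0):
            raise ValueError(f"sigma_sep must be >= 0, got {self.sigma_sep}")


@dataclass(frozen=True)
class ObservationModel:
    """Beacon/detection model linking true distance to received signal.

    The RSS--distance relationship is the log-linear calibration curve
    ``log10(distance) = b0 + b1 * RSS`` with ``b1 < 0`` (signal weakens
    with distance); detections are emitted by inverting it:
    ``RSS = (log10(d) - b0) / b1`` plus Gaussian noise.  Tags beacon at a
    fixed interval and are heard by every receiver within a hard
    detection radius.
    """

    intercept_b0: float = -1.27009
    slope_b1: float = -0.03302
    rss_noise_sd: float = 5.0
    detection_radius: float = 400.0
    beacon_interval: float = 5.0

    def __post_init__(self) -> None:
        if not (self.slope_b1 < 0):
            raise ValueError("slope_b1 must be negative (RSS weakens with distance)")
        if not (self.rss_noise_sd >= 0):
            raise ValueError("rss_noise_sd must be >= 0")
        if not (self.beacon_interval > 0):
            raise ValueError("beacon_interval must be > 0")

    def expected_rss(self, distance: np.ndarray | float) -> np.ndarray | float:
        """Noise-free RSS (dB) at a given true distance (m)."""
        d = np.maximum(np.asarray(distance, dtype=float), MIN_DISTANCE_M)
        return (np.log10(d) - self.intercept_b0) / self.slope_b1


def make_grid(
    extent_x: float,
    extent_y: float,
    spacing: float,
    layout: str = "triangular",
) -> pd.DataFrame:
    """Lay out a receiver grid over ``[0, extent_x] x [0, extent_y]``.

    ``triangular`` offsets every other row by ``spacing / 2`` with a row
    pitch of ``spacing * sqrt(3) / 2`` (equilateral packing, the layout
    used for dense wildlife-telemetry node grids); ``square`` places
    receivers on a plain lattice.

    Returns a DataFrame with columns ``receiver_id, x, y``.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    if extent_x <= 0 or extent_y <= 0:
        raise ValueError("extents must be > 0")
    if layout not in ("triangular", "square"):
        raise ValueError(f"unknown layout {layout!r}")

    eps = 1e-9 * spacing
    points: list[tuple[float, float]] = []
    if layout == "square":
        for y in np.arange(0.0, extent_y + eps, spacing):
            for x in np.arange(0.0, extent_x + eps, spacing):
                points.append((x, y))
    else:
        pitch = spacing * np.sqrt(3.0) / 2.0
        for i, y in enumerate(np.arange(0.0, extent_y + eps, pitch)):
            x0 = spacing / 2.0 if i % 2 else 0.0
            for x in np.arange(x0, extent_x + eps, spacing):
                points.append((x, y))

    return pd.DataFrame(
        {
            "receiver_id": [f"R{i:03d}" for i in range(len(points))],
            "x": [p[0] for p in points],
            "y": [p[1] for p in points],
        }
    )


def ou_paths(
    times: np.ndarray,
    tau: float,
    sigma: float,
    rng: np.random.Generator,
    n_paths: int = 1,
) -> np.ndarray:
    """Sample stationary zero-mean OU paths at the given times.

    Uses the exact discrete transition ``x[k+1] = phi * x[k] + sqrt(1 -
    phi^2) * sigma * z`` with ``phi = exp(-dt / tau)``, so stationarity
    holds for any (possibly uneven) time step.  Returns an array of
    shape ``(n_paths, len(times))``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if tau <= 0 or sigma < 0:
        raise ValueError("tau must be > 0 and sigma >= 0")

    n = times.size
    x = np.empty((n_paths, n))
    x[:, 0] = sigma * rng.standard_normal(n_paths)
    phi = np.exp(-np.diff(times) / tau)
    innov_sd = sigma * np.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal((n_paths, n - 1))
    for k in range(1, n):
        x[:, k] = phi[k - 1] * x[:, k - 1] + innov_sd[k - 1] * eps[:, k - 1]
    return x


def _regular_times(duration: float, dt: float) -> np.ndarray:
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration < dt:
        raise ValueError(f"duration ({duration}) must be >= dt ({dt})")
    n = int(np.floor(duration / dt)) + 1
    return np.arange(n) * dt


def _track_frame(tag_id: str, times: np.ndarray, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"tag_id": tag_id, "t": times, "x": x, "y": y})


def simulate_pair(
    params: MovementParams,
    duration: float,
    dt: float,
    seed: int | np.random.Generator,
    tag_ids: tuple[str, str] = ("bird1", "bird2"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the ground-truth tracks of one spatially coupled pair.

    The pair shares an OU path ``S(t)`` (SD ``sigma_pos`` per axis around
    the centre) and is split by an independent OU separation vector
    ``D(t)`` (SD ``sigma_sep``, same ``tau``): bird 1 moves at
    ``S + D/2``, bird 2 at ``S - D/2``.  ``sigma_sep = 0`` yields two
    identical tracks.
    """
    if dt > params.tau / 5.0:
        raise ValueError(
            f"dt ({dt}) must be <= tau/5 ({params.tau / 5.0}) to resolve the OU process"
        )
    times = _regular_times(duration, dt)
    rng = np.random.default_rng(seed)

    sx = ou_paths(times, params.tau, params.sigma_pos, rng)[0] + params.center_x
    sy = ou_paths(times, params.tau, params.sigma_pos, rng)[0] + params.center_y
    dx = ou_paths(times, params.tau, params.sigma_sep, rng)[0]
    dy = ou_paths(times, params.tau, params.sigma_sep, rng)[0]

    a = _track_frame(tag_ids[0], times, sx + dx / 2.0, sy + dy / 2.0)
    b = _track_frame(tag_ids[1], times, sx - dx / 2.0, sy - dy / 2.0)
    return a, b


def simulate_independent(
    params_list: Sequence[MovementParams],
    duration: float,
    dt: float,
    seed: int | np.random.Generator,
    tag_ids: Sequence[str] | None = None,
) -> list[pd.DataFrame]:
    """Simulate one independent OU track per parameter set.

    Each track is driven by its own noise stream; tracks with identical
    parameters are statistically independent.
    """
    params_list = list(params_list)
    if not params_list:
        return []
    if tag_ids is None:
        tag_ids = [f"tag{i}" for i in range(len(params_list))]
    if len(tag_ids) != len(params_list):
        raise ValueError("tag_ids must match params_list in length")

    rng = np.random.default_rng(seed)
    tracks = []
    for tag, p in zip(tag_ids, params_list):
        if dt > p.tau / 5.0:
            raise ValueError(f"dt ({dt}) must be <= tau/5 ({p.tau / 5.0})")
        times = _regular_times(duration, dt)
        x = ou_paths(times, p.tau, p.sigma_pos, rng)[0] + p.center_x
        y = ou_paths(times, p.tau, p.sigma_pos, rng)[0] + p.center_y
        tracks.append(_track_frame(tag, times, x, y))
    return tracks


def _concat_tracks(tracks: pd.DataFrame | Iterable[pd.DataFrame]) -> pd.DataFrame:
    if isinstance(tracks, pd.DataFrame):
        return tracks
    frames = list(tracks)
    if not frames:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def simulate_detections(
    tracks: pd.DataFrame | Iterable[pd.DataFrame],
    receivers: pd.DataFrame,
    obs: ObservationModel,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Emit beacon detections for every receiver in range of each beacon.

    At each beacon time (multiples of ``obs.beacon_interval`` within the
    track's time span; the true position is interpolated linearly), every
    receiver within ``obs.detection_radius`` of the tag records
    ``RSS = (log10(d) - b0)/b1 + Normal(0, rss_noise_sd)`` with the true
    distance floored at 0.1 m.

    Returns a DataFrame ``tag_id, receiver_id, t, rss`` sorted by tag,
    time, receiver.
    """
    track_df = _concat_tracks(tracks)
    if len(receivers) == 0:
        raise ValueError("receiver list is empty")
    rng = np.random.default_rng(seed)

    rx = receivers["x"].to_numpy(dtype=float)
    ry = receivers["y"].to_numpy(dtype=float)
    rids = receivers["receiver_id"].to_numpy()

    out = []
    for tag, grp in track_df.groupby("tag_id", sort=True):
        tt = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(tt) <= 0):
            raise ValueError(f"track for {tag!r} is not strictly time-sorted")
        t0 = np.ceil(tt[0] / obs.beacon_interval) * obs.beacon_interval
        beacon_t = np.arange(t0, tt[-1] + 1e-9, obs.beacon_interval)
        if beacon_t.size == 0:
            continue
        bx = np.interp(beacon_t, tt, grp["x"].to_numpy(dtype=float))
        by = np.interp(beacon_t, tt, grp["y"].to_numpy(dtype=float))

        dist = np.hypot(bx[:, None] - rx[None, :], by[:, None] - ry[None, :])
        heard = dist <= obs.detection_radius
        rss = obs.expected_rss(dist)
        if obs.rss_noise_sd > 0:
            rss = rss + rng.normal(0.0, obs.rss_noise_sd, size=dist.shape)
        ti, ri = np.nonzero(heard)
        out.append(
            pd.DataFrame(
                {
                    "tag_id": tag,
                    "receiver_id": rids[ri],
                    "t": beacon_t[ti],
                    "rss": rss[ti, ri],
                }
            )
        )

    if not out:
        return pd.DataFrame(columns=DETECTION_COLUMNS)
    det = pd.concat(out, ignore_index=True)
    return det.sort_values(["tag_id", "t", "receiver_id"], ignore_index=True)


def simulate_calibration(
    distances: Sequence[float] | None = None,
    obs: ObservationModel = ObservationModel(),
    reps_per_distance: int = 24,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a calibration exercise: repeated RSS draws at set distances.

    The default distance set is the standard field protocol (six tags held
    at 1--150 m from four receivers, i.e. 24 draws per distance).  Returns
    a DataFrame ``distance_m, rss``.
    """
    if distances is None:
        distances = CALIBRATION_DISTANCES_M
    distances = np.asarray(list(distances), dtype=float)
    if distances.size == 0:
        raise ValueError("distances is empty")
    if np.any(distances <= 0):
        raise ValueError("distances must be positive")
    if reps_per_distance < 1:
        raise ValueError("reps_per_distance must be >= 1")

    rng = np.random.default_rng(seed)
    d = np.repeat(distances, reps_per_distance)
    rss = np.asarray(obs.expected_rss(d), dtype=float)
    if obs.rss_noise_sd > 0:
        rss = rss + rng.normal(0.0, obs.rss_noise_sd, size=d.shape)
    return pd.DataFrame({"distance_m": d, "rss": rss})
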