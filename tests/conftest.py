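import numpy as np
import pandas as pd
import pytest

from pairtrack.synthetic import ObservationModel


@pytest.fixture
def noiseless_obs() -> ObservationModel:
    return ObservationModel(rss_noise_sd=0.0)


def truth_to_track(truth: pd.DataFrame, window: float = 15.0) -> pd.DataFrame:
    """Convert a ground-truth track into a localization-table-shaped frame.

    Lets trajectory/space-use operations run on exact positions, bypassing
    the localization stage.
    """
    t = truth["t"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "tag_id": truth["tag_id"].to_numpy(),
            "interval_index": np.round(t / window).astype(int),
            "t_mid": t,
            "x": truth["x"].to_numpy(dtype=float),
            "y": truth["y"].to_numpy(dtype=float),
            "ell_a": 0.0,
            "ell_b": 0.0,
            "ell_theta": 0.0,
            "n_receivers": 3,
            "n_reps": 1,
        }
    )


def grid_search_position(coords: np.ndarray, dists: np.ndarray) -> np.ndarray:
    """Independent brute-force oracle for range-based multilateration.

    Dense 1 m grid over the receiver bounding box (plus margin), refined
    to 0.01 m around the best coarse cell.
    """
    lo = coords.min(axis=0) - 50.0
    hi = coords.max(axis=0) + 50.0

    def best_on(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        xx, yy = np.meshgrid(xs, ys)
        cost = np.zeros_like(xx)
        for (cx, cy), d in zip(coords, dists):
            cost += (np.hypot(xx - cx, yy - cy) - d) ** 2
        i = np.unravel_index(np.argmin(cost), cost.shape)
        return np.array([xx[i], yy[i]])

    p = best_on(np.arange(lo[0], hi[0], 1.0), np.arange(lo[1], hi[1], 1.0))
    for step in (0.1, 0.01):
        p = best_on(
            np.arange(p[0] - 2 * step * 10, p[0] + 2 * step * 10, step),
            np.arange(p[1] - 2 * step * 10, p[1] + 2 * step * 10, step),
        )
    return p
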