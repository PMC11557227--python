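"""Track cleaning and dyadic separation summaries.

Works on localization tables (columns ``tag_id, interval_index, t_mid,
x, y, ...``).  "Simultaneous" fixes are fixes of two individuals falling
in the same localization interval (optionally within a small interval
tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DyadSummary", "filter_outliers", "pair_fixes", "summarize_dyad"]

DEFAULT_OUTLIER_THRESHOLD_M = 2500.0


@dataclass(frozen=True)
class DyadSummary:
    tag_a: str
    tag_b: str
    median_separation: float  # NaN when no simultaneous fixes exist
    frac_simultaneous: float
    median_gap: float  # seconds, nearest partner fix
    n_paired: int


def filter_outliers(
    localizations: pd.DataFrame, threshold: float = DEFAULT_OUTLIER_THRESHOLD_M
) -> pd.DataFrame:
    """Drop fixes farther than ``threshold`` from an individual's median point.

    The median point is component-wise (marginal medians of x and y),
    computed per tag.  Order is preserved.
    """
    if localizations.empty:
        raise ValueError("no fixes to filter")
    keep = np.zeros(len(localizations), dtype=bool)
    for _, grp in localizations.groupby("tag_id"):
        mx = grp["x"].median()
        my = grp["y"].median()
        dist = np.hypot(grp["x"] - mx, grp["y"] - my)
        keep[grp.index[dist <= threshold]] = True
    return localizations.loc[keep].reset_index(drop=True)


def pair_fixes(
    track_a: pd.DataFrame, track_b: pd.DataFrame, tolerance: int = 0
) -> pd.DataFrame:
    """Match simultaneous fixes and compute their separation distance.

    With ``tolerance = 0`` fixes sharing an ``interval_index`` are
    matched; with ``tolerance = k`` each fix of A is matched to the
    nearest fix of B within k intervals (ties to the earlier one).
    Returns ``tag_a, tag_b, interval_index, t_mid, separation``.
    """
    if track_a.empty or track_b.empty:
        return pd.DataFrame(columns=["tag_a", "tag_b", "interval_index", "t_mid", "separation"])
    a = track_a.sort_values("interval_index")
    b = track_b.sort_values("interval_index")
    if tolerance == 0:
        merged = a.merge(b, on="interval_index", suffixes=("_a", "_b"))
    else:
        merged = pd.merge_asof(
            a,
            b,
            on="interval_index",
            direction="nearest",
            tolerance=tolerance,
            suffixes=("_a", "_b"),
        ).dropna(subset=["x_b"])
    if merged.empty:
        return pd.DataFrame(columns=["tag_a", "tag_b", "interval_index", "t_mid", "separation"])
    sep = np.hypot(merged["x_a"] - merged["x_b"], merged["y_a"] - merged["y_b"])
    return pd.DataFrame(
        {
            "tag_a": merged["tag_id_a"].to_numpy(),
            "tag_b": merged["tag_id_b"].to_numpy(),
            "interval_index": merged["interval_index"].to_numpy(),
            "t_mid": merged.get("t_mid_a", merged["interval_index"]).to_numpy(),
            "separation": sep.to_numpy(),
        }
    )


def _nearest_gaps(t_from: np.ndarray, t_to: np.ndarray) -> np.ndarray:
    """For each time in t_from, the absolute gap to the nearest time in t_to."""
    t_to = np.sort(t_to)
    pos = np.searchsorted(t_to, t_from)
    left = np.abs(t_from - t_to[np.clip(pos - 1, 0, t_to.size - 1)])
    right = np.abs(t_from - t_to[np.clip(pos, 0, t_to.size - 1)])
    return np.minimum(left, right)


def summarize_dyad(
    track_a: pd.DataFrame, track_b: pd.DataFrame, tolerance: int = 0
) -> DyadSummary:
    """Separation summaries for one dyad.

    ``frac_simultaneous`` divides the number of matched fixes by the
    mean of the two individuals' fix counts; ``median_gap`` is the median
    over all fixes (both directions) of the time to the partner's nearest
    fix.
    """
    if track_a.empty or track_b.empty:
        raise ValueError("both tracks need at least one fix")
    paired = pair_fixes(track_a, track_b, tolerance=tolerance)
    n_paired = len(paired)
    med_sep = float(paired["separation"].median()) if n_paired else float("nan")
    frac = n_paired / ((len(track_a) + len(track_b)) / 2.0)

    ta = track_a["t_mid"].to_numpy(dtype=float)
    tb = track_b["t_mid"].to_numpy(dtype=float)
    gaps = np.concatenate([_nearest_gaps(ta, tb), _nearest_gaps(tb, ta)])
    return DyadSummary(
        tag_a=str(track_a["tag_id"].iloc[0]),
        tag_b=str(track_b["tag_id"].iloc[0]),
        median_separation=med_sep,
        frac_simultaneous=float(frac),
        median_gap=float(np.median(gaps)),
        n_paired=int(n_paired),
    )
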