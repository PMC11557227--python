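"""Plain-text readers/writers for the pipeline's tabular and raster formats.

CSV schemas: receivers ``receiver_id,x,y``; detections
``tag_id,receiver_id,t,rss``; calibration ``distance_m,rss``; truth
``tag_id,t,x,y``; localizations as produced by
:func:`pairtrack.localization.localize_all`.  Utilization distributions
export to the ESRI ASCII raster dialect and home-range contours to
GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .space_use import UtilizationDistribution

__all__ = [
    "read_receivers",
    "read_detections",
    "read_calibration",
    "read_localizations",
    "write_table",
    "write_ascii_raster",
    "read_ascii_raster",
    "write_home_range_geojson",
]

CSV_FLOAT_FORMAT = "%.10g"


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_receivers(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ["receiver_id", "x", "y"])
    if df["receiver_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate receiver ids")
    return df


def read_detections(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ["tag_id", "receiver_id", "t", "rss"])


def read_calibration(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ["distance_m", "rss"])


def read_localizations(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ["tag_id", "t_mid", "x", "y"])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_ascii_raster(ud: UtilizationDistribution, path: str | Path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid of the UD mass (row 1 = northernmost row)."""
    ny, nx = ud.mass.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {ud.origin_x:.6f}\n")
        fh.write(f"yllcorner {ud.origin_y:.6f}\n")
        fh.write(f"cellsize {ud.cell:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, ud.mass[::-1], fmt="%.8e")


def read_ascii_raster(path: str | Path) -> UtilizationDistribution:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        mass = np.loadtxt(fh)
    mass = np.atleast_2d(mass)[::-1]
    return UtilizationDistribution(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell=header["cellsize"],
        mass=mass,
    )


def write_home_range_geojson(
    ud: UtilizationDistribution, path: str | Path, level: float = 0.95
) -> None:
    """Contour polygons of the smallest cell set holding ``level`` mass."""
    from shapely.geometry import Polygon, mapping
    from skimage import measure

    flat = np.sort(ud.mass.ravel())[::-1]
    csum = np.cumsum(flat)
    n_cells = int(np.searchsorted(csum, level - 1e-12) + 1)
    threshold = flat[min(n_cells, flat.size) - 1]

    polys = []
    for contour in measure.find_contours(ud.mass, threshold):
        # contour vertices are (row, col) in cell units
        xs = ud.origin_x + (contour[:, 1] + 0.5) * ud.cell
        ys = ud.origin_y + (contour[:, 0] + 0.5) * ud.cell
        if len(xs) >= 4:
            poly = Polygon(zip(xs, ys))
            if poly.is_valid and poly.area > 0:
                polys.append(poly)

    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"level": level, "mass_threshold": float(threshold)},
                "geometry": mapping(p),
            }
            for p in polys
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)
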