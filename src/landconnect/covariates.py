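"""Buffered landscape covariates around genetic nodes.

For each node and each buffer radius (6, 20 and 120 km in the full-scale
analysis), the mean and population standard deviation of (a) the cost
surface and (b) the current-density surface are extracted over all cells
whose centers fall within the radius — 12 landscape covariates per node
(2 statistics x 2 surfaces x 3 extents).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .circuit import CurrentDensityMap
from .raster import Raster

__all__ = ["buffer_stats", "assemble_records", "covariate_columns", "DEFAULT_RADII_M"]

log = logging.getLogger(__name__)

DEFAULT_RADII_M: tuple[float, ...] = (6_000.0, 20_000.0, 120_000.0)


def buffer_stats(
    surface: Raster, center: tuple[float, float], radius_m: float
) -> tuple[float, float, int]:
    """Mean, population SD and cell count within a circular buffer.

    Membership is center-in-circle over non-NoData cells; buffers
    truncated by the raster edge are flagged with a warning.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    cx, cy = center
    xmin, ymin, xmax, ymax = surface.extent
    if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
        raise ValueError(f"buffer center {center} outside raster extent")
    X, Y = surface.cell_centers()
    inside = ((X - cx) ** 2 + (Y - cy) ** 2 <= radius_m**2) & np.isfinite(surface.data)
    n = int(inside.sum())
    if n == 0:
        raise ValueError(f"no valid cells within {radius_m} m of {center}")
    if (cx - radius_m < xmin or cx + radius_m > xmax
            or cy - radius_m < ymin or cy + radius_m > ymax):
        warnings.warn(f"buffer at {center} r={radius_m} truncated by raster edge")
    vals = surface.data[inside]
    return float(vals.mean()), float(vals.std(ddof=0)), n


def covariate_columns(radii_m: tuple[float, ...]) -> list[str]:
    """Canonical covariate column names for a set of radii (km labels)."""
    cols = []
    for r in radii_m:
        km = f"{r / 1000:g}"
        cols += [f"mean_cost_{km}km", f"sd_cost_{km}km",
                 f"mean_current_{km}km", f"sd_current_{km}km"]
    return cols


def assemble_records(
    nodes: pd.DataFrame,
    cost: Raster,
    current: CurrentDensityMap | Raster,
    radii_m: tuple[float, ...] = DEFAULT_RADII_M,
) -> pd.DataFrame:
    """One record per node: response, coordinates, n, and the buffered
    landscape covariates at every radius.

    ``nodes`` is the node-connectivity table (site_id, species, x, y, n,
    connectivity_z, ...).  Nodes outside the raster extent are dropped
    with a log entry.  Globally z-scored covariate copies (``z_`` prefix)
    are attached for inspection; model fitting re-standardizes within its
    own node subset.  The covariate correlation matrix is attached as
    ``result.attrs["correlations"]``.
    """
    cur = current.current if isinstance(current, CurrentDensityMap) else current
    records = []
    dropped = []
    for r in nodes.itertuples():
        rec = {
            "site_id": r.site_id,
            "species": getattr(r, "species", "all"),
            "x": float(r.x),
            "y": float(r.y),
            "n": float(getattr(r, "n", np.nan)),
            "connectivity_z": float(getattr(r, "connectivity_z", np.nan)),
            "mean_inverse_edge_weight": float(
                getattr(r, "mean_inverse_edge_weight", np.nan)
            ),
        }
        try:
            for radius in radii_m:
                km = f"{radius / 1000:g}"
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mc, sc, _ = buffer_stats(cost, (rec["x"], rec["y"]), radius)
                    mu, su, _ = buffer_stats(cur, (rec["x"], rec["y"]), radius)
                rec[f"mean_cost_{km}km"] = mc
                rec[f"sd_cost_{km}km"] = sc
                rec[f"mean_current_{km}km"] = mu
                rec[f"sd_current_{km}km"] = su
        except ValueError as exc:
            dropped.append((r.site_id, str(exc)))
            continue
        records.append(rec)
    for sid, why in dropped:
        log.warning("node %s dropped from covariate table: %s", sid, why)
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("no nodes fell inside the raster extent")
    cov_cols = covariate_columns(radii_m)
    for c in cov_cols:
        vals = df[c].to_numpy()
        sd = vals.std(ddof=1)
        df[f"z_{c}"] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    df.attrs["correlations"] = df[cov_cols].corr()
    df.attrs["radii_m"] = tuple(radii_m)
    return df
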