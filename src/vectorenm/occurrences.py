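"""Occurrence ingestion, spatial thinning, splitting, and the accessible area.

Occurrence records are kept as a pandas DataFrame with columns
``species, longitude, latitude`` plus an optional ``split`` label in
{calibration, evaluation, independent}.  All distances are great-circle
(haversine) kilometres on a spherical Earth — degrees are never
converted to km by a fixed factor.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Grid, haversine_km

__all__ = [
    "load_occurrences",
    "thin",
    "split_calibration",
    "build_accessible_area",
    "AccessibleArea",
]


class OccurrenceFormatError(ValueError):
    """Input table lacks the required columns."""


class OccurrenceValidationError(ValueError):
    """One or more records have out-of-range coordinates."""

    def __init__(self, bad_rows: pd.DataFrame):
        self.bad_rows = bad_rows
        super().__init__(
            f"{len(bad_rows)} record(s) with out-of-range coordinates "
            f"(rows {list(bad_rows.index)}):\n{bad_rows.to_string()}"
        )


def load_occurrences(path: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Load and validate an occurrence table.

    Accepts a CSV path (or a DataFrame, passed through the same checks).
    Exact-coordinate duplicates are dropped; coordinates outside
    [-180, 180] x [-90, 90] raise a record-level error listing every
    offending row; an empty table is returned with a warning.
    """
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        df = pd.read_csv(path)
    missing = {"longitude", "latitude"} - set(df.columns)
    if missing:
        raise OccurrenceFormatError(f"missing required column(s): {sorted(missing)}")
    if "species" not in df.columns:
        df["species"] = "unknown"
    if df.empty:
        warnings.warn("occurrence table is empty")
        return df.reset_index(drop=True)
    df["longitude"] = pd.to_numeric(df["longitude"])
    df["latitude"] = pd.to_numeric(df["latitude"])
    bad = df[
        ~df["longitude"].between(-180, 180)
        | ~df["latitude"].between(-90, 90)
        | df["longitude"].isna()
        | df["latitude"].isna()
    ]
    if len(bad):
        raise OccurrenceValidationError(bad)
    df = df.drop_duplicates(subset=["longitude", "latitude"], keep="first")
    return df.reset_index(drop=True)


def _pairwise_km(df: pd.DataFrame) -> np.ndarray:
    lon = df["longitude"].to_numpy()
    lat = df["latitude"].to_numpy()
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def thin(
    occ: pd.DataFrame, d_km: float, seed: int = 0, restarts: int = 100
) -> pd.DataFrame:
    """Spatially thin records so all pairwise distances are >= ``d_km``.

    Strategy (randomized-restart greedy): within each restart, while any
    pair of surviving records is closer than ``d_km``, take the closest
    violating pair and remove the member with more neighbours within
    ``d_km`` (ties broken at random).  The largest surviving set over
    ``restarts`` restarts is returned.  Reproducible given ``seed``.
    """
    if d_km <= 0:
        raise ValueError("d_km must be positive")
    n = len(occ)
    if n <= 1:
        return occ.reset_index(drop=True)
    D = _pairwise_km(occ)
    np.fill_diagonal(D, np.inf)
    viol = D < d_km
    if not viol.any():
        return occ.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(max(1, restarts)):
        alive = np.ones(n, dtype=bool)
        v = viol.copy()
        while True:
            sub = np.where(alive)[0]
            vs = v[np.ix_(sub, sub)]
            if not vs.any():
                break
            ds = D[np.ix_(sub, sub)]
            ds = np.where(vs, ds, np.inf)
            i, j = np.unravel_index(np.argmin(ds), ds.shape)
            a, b = sub[i], sub[j]
            deg_a, deg_b = v[a][alive].sum(), v[b][alive].sum()
            if deg_a > deg_b:
                drop = a
            elif deg_b > deg_a:
                drop = b
            else:
                drop = a if rng.random() < 0.5 else b
            alive[drop] = False
        if best is None or alive.sum() > best.sum():
            best = alive
    return occ.loc[np.asarray(best)].reset_index(drop=True)


def split_calibration(
    occ: pd.DataFrame, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint calibration/evaluation split.

    ``|calibration| = round(fraction * n)`` with round-half-up (so 101
    records at fraction 0.5 give a 51/50 split).  Raises if fewer than
    two records.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(occ)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_cal = int(np.floor(fraction * n + 0.5))
    n_cal = min(max(n_cal, 1), n - 1)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    cal = occ.iloc[np.sort(idx[:n_cal])].copy()
    ev = occ.iloc[np.sort(idx[n_cal:])].copy()
    cal["split"] = "calibration"
    ev["split"] = "evaluation"
    return cal.reset_index(drop=True), ev.reset_index(drop=True)


class AccessibleArea:
    """Boolean mask of cells whose centers lie within B km of an occurrence."""

    def __init__(self, mask: np.ndarray, grid: Grid, buffer_km: float):
        self.mask = np.asarray(mask, dtype=bool)
        self.grid = grid
        self.buffer_km = buffer_km
        if self.mask.shape != grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def build_accessible_area(
    occ: pd.DataFrame, buffer_km: float, grid: Grid
) -> AccessibleArea:
    """Accessible-area (M) mask: union of ``buffer_km`` haversine disks.

    A cell is inside iff its center is within ``buffer_km`` of at least
    one occurrence; with ``buffer_km = 0`` only the cells containing
    occurrences are inside.
    """
    if len(occ) == 0:
        raise ValueError("cannot build an accessible area from zero occurrences")
    if buffer_km < 0:
        raise ValueError("buffer_km must be >= 0")
    lon_g, lat_g = grid.cell_centers()
    mask = np.zeros(grid.shape, dtype=bool)
    if buffer_km == 0:
        for lon, lat in zip(occ["longitude"], occ["latitude"]):
            r, c = grid.cell_of(lon, lat)
            mask[r, c] = True
        return AccessibleArea(mask, grid, buffer_km)
    # chunk over occurrences to bound memory on big grids
    lons = occ["longitude"].to_numpy()
    lats = occ["latitude"].to_numpy()
    for start in range(0, len(lons), 64):
        sl = slice(start, start + 64)
        d = haversine_km(
            lon_g[None, :, :], lat_g[None, :, :],
            lons[sl, None, None], lats[sl, None, None],
        )
        mask |= (d <= buffer_km).any(axis=0)
    return AccessibleArea(mask, grid, buffer_km)
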