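"""Cattle-exposure overlay: percent modification of vector suitability by
zoogeographic region and cattle-abundance category.

The percent-modification statistic relates range *gain* to the
present-day suitable range within each (region, abundance-category)
stratum:

    100 * (# gain cells in stratum) / (# present-suitable cells in stratum)

where gain cells are those classified gain-strong (and also gain-weak
when ``strong_only=False``) in the five-class change map.  Because the
denominator is the present-day suitable area, values can exceed 100%
where a stratum's suitable range is projected to grow beyond its
current size.  The "both" scenario rows use the union of the gain
cells of the two emissions scenarios, which is why they can exceed
either individual scenario.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import GridMismatchError

__all__ = [
    "DEFAULT_BREAKPOINTS",
    "CattleCategories",
    "categorize_cattle",
    "exposure_table",
    "flag_high",
]

#: lower edges of the seven abundance categories, head per 10 km^2
DEFAULT_BREAKPOINTS = (0.0, 1.0, 5.0, 10.0, 20.0, 50.0, 100.0)


def category_labels(breakpoints: Sequence[float] = DEFAULT_BREAKPOINTS) -> list[str]:
    bp = list(breakpoints)
    labels = [f"{_fmt(a)}-{_fmt(b)}" for a, b in zip(bp[:-1], bp[1:])]
    labels.append(f">{_fmt(bp[-1])}")
    return labels


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclasses.dataclass
class CattleCategories:
    """Categorical cattle-abundance raster: integer codes 0..n_cat-1,
    -1 on cells without cattle data."""

    codes: np.ndarray
    breakpoints: tuple[float, ...]
    labels: list[str]


def categorize_cattle(
    cattle: np.ndarray, breakpoints: Sequence[float] = DEFAULT_BREAKPOINTS
) -> CattleCategories:
    """Bin a cattle-density raster into abundance categories.

    Intervals are ``[low, high)`` with a final open-ended ``[last, inf)``
    category, so a density of exactly 100 falls in the ">100" class.
    Negative densities are an error; NaN cells get code -1.
    """
    bp = tuple(float(b) for b in breakpoints)
    if any(b2 <= b1 for b1, b2 in zip(bp[:-1], bp[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    cattle = np.asarray(cattle, float)
    valid = ~np.isnan(cattle)
    if np.any(cattle[valid] < bp[0]):
        raise ValueError("cattle density below the first breakpoint (negative?)")
    codes = np.full(cattle.shape, -1, dtype=int)
    codes[valid] = np.digitize(cattle[valid], bp[1:], right=False)
    return CattleCategories(codes, bp, category_labels(bp))


def exposure_table(
    present_binary: np.ndarray,
    change_maps: Mapping[str, np.ndarray],
    categories: CattleCategories,
    regions: np.ndarray,
    region_names: Mapping[int, str] | None = None,
    strong_only: bool = True,
) -> pd.DataFrame:
    """Percent-modification table: (scenario x region) rows, category columns.

    ``change_maps`` maps scenario name (e.g. ``"rcp45"``, ``"rcp85"``)
    to a five-class change raster; a ``"both"`` row is added using the
    union of gain cells across all given scenarios.  Strata with zero
    present-suitable cells are reported as NaN (undefined), not 0.  The
    ``average`` column is the arithmetic mean of the defined category
    cells in its row.
    """
    pb = np.asarray(present_binary, bool)
    regions = np.asarray(regions)
    if not (pb.shape == regions.shape == categories.codes.shape):
        raise GridMismatchError("exposure rasters differ in shape")
    gain_codes = (4,) if strong_only else (3, 4)
    gains: dict[str, np.ndarray] = {}
    for scen, cm in change_maps.items():
        cm = np.asarray(cm)
        if cm.shape != pb.shape:
            raise GridMismatchError(f"change map {scen!r} differs in shape")
        gains[scen] = np.isin(cm, gain_codes)
    if len(gains) > 1:
        union = np.zeros(pb.shape, bool)
        for g in gains.values():
            union |= g
        gains["both"] = union
    region_ids = sorted(int(r) for r in np.unique(regions) if r > 0)
    region_names = region_names or {r: f"region{r}" for r in region_ids}
    n_cat = len(categories.labels)
    rows = []
    any_stratum = False
    for scen, gain in gains.items():
        for rid in region_ids:
            in_region = regions == rid
            row: dict[str, object] = {
                "scenario": scen,
                "region": region_names.get(rid, str(rid)),
            }
            vals = []
            for ci, lab in enumerate(categories.labels):
                stratum = in_region & (categories.codes == ci)
                denom = int((stratum & pb).sum())
                if denom == 0:
                    row[lab] = np.nan
                else:
                    any_stratum = True
                    num = int((stratum & gain).sum())
                    row[lab] = 100.0 * num / denom
                    vals.append(row[lab])
            row["average"] = float(np.mean(vals)) if vals else np.nan
            rows.append(row)
    if not any_stratum:
        raise ValueError("no stratum contains present-suitable cells")
    cols = ["scenario", "region", *categories.labels, "average"]
    return pd.DataFrame(rows, columns=cols)


def flag_high(table: pd.DataFrame, cutoff_percent: float = 10.0) -> pd.DataFrame:
    """Boolean flags for cells exceeding the highlighting cutoff (default
    10%, the convention used to italicize large increases)."""
    num = table.drop(columns=["scenario", "region"])
    flags = num > cutoff_percent
    out = table[["scenario", "region"]].copy()
    for c in num.columns:
        out[c] = flags[c]
    return out
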