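"""Environmental layer management: collinearity filtering, variable-set
enumeration, delta-method downscaling, and cropping to the accessible area.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grids import Grid, GridMismatchError, LayerStack
from .occurrences import AccessibleArea

__all__ = [
    "pearson_filter",
    "enumerate_variable_sets",
    "delta_downscale",
    "crop_stack",
]


def pearson_filter(
    stack: LayerStack,
    r_max: float = 0.80,
    mask: np.ndarray | None = None,
) -> list[str]:
    """Greedily drop layers until no retained pair has |r| >= ``r_max``.

    Pearson correlations are computed over the valid (optionally further
    masked) cells.  While a violating pair exists, the layer with the
    larger mean absolute correlation to all other remaining layers is
    dropped; ties are broken by dropping the lexicographically later
    name, which makes the result order-stable.  Constant (zero-variance)
    layers are removed up front with a warning.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 layers to filter")
    m = stack.mask if mask is None else (stack.mask & mask)
    if not m.any():
        raise ValueError("mask is empty")
    names = list(stack.names)
    X = stack.table(mask=m)
    sd = X.std(axis=0)
    const = [n for n, s in zip(names, sd) if s == 0]
    if const:
        warnings.warn(f"constant layer(s) removed: {const}")
        keep = [i for i, n in enumerate(names) if n not in const]
        X = X[:, keep]
        names = [names[i] for i in keep]
    if len(names) < 2:
        return names
    R = np.corrcoef(X, rowvar=False)
    active = list(range(len(names)))
    while True:
        sub = np.abs(R[np.ix_(active, active)])
        np.fill_diagonal(sub, 0.0)
        if sub.max() < r_max:
            break
        viol = {i for k, i in enumerate(active) if (sub[k] >= r_max).any()}
        # mean |r| of each violating layer to all other active layers
        mean_abs = {
            i: sub[active.index(i)].sum() / (len(active) - 1) for i in viol
        }
        top = max(mean_abs.values())
        cands = sorted(
            (names[i] for i in viol if np.isclose(mean_abs[i], top, atol=1e-12)),
        )
        drop_name = cands[-1]
        active.remove(names.index(drop_name))
    return [names[i] for i in active]


def enumerate_variable_sets(
    names: Sequence[str], min_size: int = 2
) -> list[tuple[str, ...]]:
    """All subsets of the layer names of size >= ``min_size``.

    With v names the count is ``2^v - sum_{i<min_size} C(v, i)``; seven
    retained variables at min_size 2 give the canonical 120 candidate
    variable sets.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    names = list(names)
    if len(names) < min_size:
        warnings.warn(
            f"only {len(names)} layer(s) available, fewer than min_size={min_size}"
        )
        return []
    out: list[tuple[str, ...]] = []
    for size in range(min_size, len(names) + 1):
        out.extend(itertools.combinations(names, size))
    return out


def delta_downscale(
    coarse_baseline: np.ndarray,
    coarse_future: np.ndarray,
    fine_baseline: np.ndarray,
    coarse_grid: Grid,
    fine_grid: Grid,
    clip: tuple[float, float] | None = None,
) -> np.ndarray:
    """Delta-method downscaling with additive anomalies.

    The coarse anomaly ``coarse_future - coarse_baseline`` is bilinearly
    interpolated at fine-cell centers and added to the fine baseline.
    Fine centers beyond the outermost coarse cell centers (the half-cell
    edge band of a nested grid) take the edge value.  ``clip`` bounds
    the output (e.g. (0, 100) for relative humidity in percent).
    """
    coarse_baseline = np.asarray(coarse_baseline, float)
    coarse_future = np.asarray(coarse_future, float)
    if coarse_baseline.shape != coarse_grid.shape or coarse_future.shape != coarse_grid.shape:
        raise GridMismatchError("coarse arrays do not match the coarse grid")
    if np.asarray(fine_baseline).shape != fine_grid.shape:
        raise GridMismatchError("fine baseline does not match the fine grid")
    fx0 = fine_grid.xll
    fx1 = fine_grid.xll + fine_grid.ncols * fine_grid.cellsize
    cx0 = coarse_grid.xll
    cx1 = coarse_grid.xll + coarse_grid.ncols * coarse_grid.cellsize
    fy0, fy1 = fine_grid.yll, fine_grid.yll + fine_grid.nrows * fine_grid.cellsize
    cy0, cy1 = coarse_grid.yll, coarse_grid.yll + coarse_grid.nrows * coarse_grid.cellsize
    eps = 1e-9
    if fx0 < cx0 - eps or fx1 > cx1 + eps or fy0 < cy0 - eps or fy1 > cy1 + eps:
        raise GridMismatchError("fine grid extent is not nested in the coarse extent")
    anomaly = coarse_future - coarse_baseline
    # coarse cell-center coordinates; row 0 is northernmost so latitude descends
    clon = cx0 + (np.arange(coarse_grid.ncols) + 0.5) * coarse_grid.cellsize
    clat = cy0 + (coarse_grid.nrows - np.arange(coarse_grid.nrows) - 0.5) * coarse_grid.cellsize
    interp = RegularGridInterpolator(
        (clat[::-1], clon), anomaly[::-1, :], method="linear",
        bounds_error=False, fill_value=None,
    )
    flon, flat = fine_grid.cell_centers()
    # clamp to the coarse center hull: nearest-edge instead of extrapolation
    q_lat = np.clip(flat, clat[-1], clat[0])
    q_lon = np.clip(flon, clon[0], clon[-1])
    out = np.asarray(fine_baseline, float) + interp(
        np.stack([q_lat.ravel(), q_lon.ravel()], axis=1)
    ).reshape(fine_grid.shape)
    if clip is not None:
        out = np.clip(out, clip[0], clip[1])
    return out


def crop_stack(stack: LayerStack, area: AccessibleArea) -> LayerStack:
    """Restrict a stack's validity mask to the accessible area."""
    if area.grid != stack.grid:
        raise GridMismatchError("accessible area is on a different grid")
    new_mask = stack.mask & area.mask
    if not new_mask.any():
        raise ValueError("accessible area does not intersect the stack's valid cells")
    return LayerStack(stack.grid, stack.layers, new_mask)
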