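"""Model transfer: bootstrap-median projection, extrapolation risk (MOP),
binarization, climate-model ensemble agreement, and change classification.

The final model is the per-cell median over bootstrap replicates of the
best calibration; it is projected to the present baseline and to every
future (GCM, RCP, period) stack.  Projections are binarized with the
E-percentile threshold of the calibration-occurrence suitabilities from
the present-day model, the *same* threshold being applied to every
future projection so binary maps are comparable across time.  Ensemble
agreement counts suitable votes per cell across GCMs; change classes
combine the present binary map with that count.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .grids import Grid, GridMismatchError, LayerStack
from .maxent import MaxentNiche

__all__ = [
    "bootstrap_median_model",
    "mop",
    "MOPSurface",
    "e_threshold",
    "binarize",
    "agreement",
    "AgreementMap",
    "classify_change",
    "CHANGE_CLASSES",
]

#: integer codes of the five present-vs-future change classes
CHANGE_CLASSES = {
    0: "unsuitable",              # white
    1: "suitable-weakening",      # light blue: suitable now, < cutoff GCMs agree
    2: "stable-suitable-strong",  # dark blue: suitable now and >= cutoff agree
    3: "gain-weak",               # pink: unsuitable now, 1..cutoff-1 GCMs agree
    4: "gain-strong",             # red: unsuitable now, >= cutoff GCMs agree
}


def e_threshold(calib_values: np.ndarray, E: float = 0.05) -> float:
    """E-percentile binarization threshold.

    The threshold is the ``(floor(E * n) + 1)``-th smallest calibration
    suitability, i.e. the largest observed value whose induced
    calibration omission does not exceed E.
    """
    vals = np.sort(np.asarray(calib_values, float))
    if vals.size == 0:
        raise ValueError("need at least one calibration suitability value")
    idx = int(np.floor(E * vals.size))
    return float(vals[min(idx, vals.size - 1)])


def binarize(
    prediction: np.ndarray, calib_values: np.ndarray, E: float = 0.05
) -> tuple[np.ndarray, float]:
    """Binarize a suitability raster at the E-percentile calibration threshold.

    Returns ``(binary, threshold)``; ``binary`` is True where
    ``prediction >= threshold`` (NaN cells are False).
    """
    thr = e_threshold(calib_values, E)
    with np.errstate(invalid="ignore"):
        return np.asarray(prediction) >= thr, thr


def bootstrap_median_model(
    stack: LayerStack,
    calib_lonlat: np.ndarray,
    target_stacks: Mapping[object, LayerStack],
    classes: str = "lq",
    rm: float = 1.0,
    knots: int = 9,
    n_boot: int = 10,
    seed: int = 0,
    max_background: int = 10_000,
    resample: bool = True,
) -> dict[object, np.ndarray]:
    """Per-cell median over bootstrap replicates, for every target stack.

    ``n_boot`` models are fitted on with-replacement resamples (same n)
    of the calibration occurrences against the calibration stack's
    background; each is projected (cloglog, clamped) onto every target
    stack, and the per-cell median across surviving replicates is
    returned per target.  A replicate whose fit raises is dropped with
    a warning; at least ``ceil(n_boot / 2)`` replicates must survive.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    calib_lonlat = np.asarray(calib_lonlat, float)
    n = calib_lonlat.shape[0]
    rng = np.random.default_rng(seed)
    preds: dict[object, list[np.ndarray]] = {k: [] for k in target_stacks}
    failures = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n) if resample else np.arange(n)
        try:
            model = MaxentNiche.from_stack(
                stack, calib_lonlat[idx], classes=classes, knots=knots,
                max_background=max_background, seed=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(rm=rm)
            for key, tgt in target_stacks.items():
                preds[key].append(res.predict(tgt, scale="cloglog", clamp=True))
        except Exception as exc:
            failures += 1
            warnings.warn(f"bootstrap replicate {b} failed: {exc}")
    survived = n_boot - failures
    if survived < int(np.ceil(n_boot / 2)):
        raise RuntimeError(
            f"only {survived} of {n_boot} bootstrap replicates succeeded"
        )
    return {k: np.nanmedian(np.stack(v), axis=0) for k, v in preds.items()}


@dataclasses.dataclass
class MOPSurface:
    """Mobility-oriented parity surface.

    ``similarity`` lies in [0, 1] (1 = environment identical to the
    nearest part of the calibration cloud); ``strict_extrapolation``
    flags cells where any variable falls outside the calibration
    min-max range — similarity is still recorded there, but downstream
    suitability interpretation should mask those cells.
    """

    similarity: np.ndarray
    strict_extrapolation: np.ndarray
    distance: np.ndarray


def mop(
    calib_stack: LayerStack,
    proj_stack: LayerStack,
    reference_fraction: float = 0.1,
    sample_cap: int = 5000,
    seed: int = 0,
) -> MOPSurface:
    """Mobility-oriented parity between calibration and projection clouds.

    Per projection cell, Euclidean distance in the space of variables
    standardized by the calibration range (max - min) is computed to
    every calibration cell (uniformly subsampled to ``sample_cap`` when
    larger, seeded); the MOP distance is the mean of the nearest
    ``reference_fraction`` of those distances, and similarity is
    ``1 - distance / max(distance over projection cells)``.
    """
    if not 0 < reference_fraction <= 1:
        raise ValueError("reference_fraction must be in (0, 1]")
    if sorted(calib_stack.names) != sorted(proj_stack.names):
        raise GridMismatchError("calibration and projection stacks differ in variables")
    names = calib_stack.names
    C = calib_stack.table()
    if C.shape[0] == 0:
        raise ValueError("calibration mask is empty")
    if C.shape[0] > sample_cap:
        rng = np.random.default_rng(seed)
        C = C[rng.choice(C.shape[0], size=sample_cap, replace=False)]
    lo = calib_stack.table().min(axis=0)
    hi = calib_stack.table().max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    Cn = (C - lo) / span
    rows, cols = np.where(proj_stack.mask)
    P = np.column_stack([proj_stack[n][rows, cols] for n in names])
    strict = ((P < lo) | (P > hi)).any(axis=1)
    Pn = (P - lo) / span
    k = max(1, int(np.ceil(reference_fraction * Cn.shape[0])))
    dist = np.empty(Pn.shape[0])
    chunk = max(1, 2_000_000 // max(Cn.shape[0], 1))
    for s in range(0, Pn.shape[0], chunk):
        D = cdist(Pn[s : s + chunk], Cn)
        part = np.partition(D, k - 1, axis=1)[:, :k]
        dist[s : s + chunk] = part.mean(axis=1)
    dmax = dist.max()
    sim = 1.0 - dist / dmax if dmax > 0 else np.ones_like(dist)
    shape = proj_stack.grid.shape
    sim_r = np.full(shape, np.nan)
    dist_r = np.full(shape, np.nan)
    strict_r = np.zeros(shape, dtype=bool)
    sim_r[rows, cols] = sim
    dist_r[rows, cols] = dist
    strict_r[rows, cols] = strict
    return MOPSurface(sim_r, strict_r, dist_r)


@dataclasses.dataclass
class AgreementMap:
    """Per-cell count of GCMs voting a cell suitable, with the agreement
    cutoff (default ceil(0.6 * G))."""

    counts: np.ndarray
    n_models: int
    cutoff: int


def agreement(
    binaries: Sequence[np.ndarray], cutoff_frac: float = 0.6
) -> AgreementMap:
    """Sum suitable votes across an ensemble of binary maps."""
    if len(binaries) < 1:
        raise ValueError("need at least one binary raster")
    shape = np.asarray(binaries[0]).shape
    for b in binaries[1:]:
        if np.asarray(b).shape != shape:
            raise GridMismatchError("ensemble binary rasters differ in shape")
    counts = np.sum([np.asarray(b, bool) for b in binaries], axis=0)
    G = len(binaries)
    cutoff = int(np.ceil(cutoff_frac * G))
    return AgreementMap(counts.astype(int), G, cutoff)


def classify_change(
    present_binary: np.ndarray, agree: AgreementMap
) -> np.ndarray:
    """Five-class present-vs-future change map (see CHANGE_CLASSES).

    present suitable & count >= cutoff -> stable-suitable-strong (2);
    present suitable & count <  cutoff -> suitable-weakening (1);
    present unsuitable & count >= cutoff -> gain-strong (4);
    present unsuitable & 0 < count < cutoff -> gain-weak (3);
    otherwise unsuitable (0).
    """
    pb = np.asarray(present_binary, bool)
    if pb.shape != agree.counts.shape:
        raise GridMismatchError("present binary and agreement map differ in shape")
    c = agree.counts
    out = np.zeros(pb.shape, dtype=int)
    out[pb & (c >= agree.cutoff)] = 2
    out[pb & (c < agree.cutoff)] = 1
    out[~pb & (c >= agree.cutoff)] = 4
    out[~pb & (c > 0) & (c < agree.cutoff)] = 3
    return out
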