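"""Candidate-model evaluation and selection.

Candidates (variable set x feature-class subset x regularization
multiplier) are screened by the three-stage rule used throughout the
niche-modelling calibration literature:

1. **significance** — partial ROC: bootstrap AUC ratios restricted to
   the high-sensitivity region (sensitivity >= 1 - E); p is the
   fraction of bootstrap ratios <= 1;
2. **performance** — omission rate of evaluation occurrences at the
   E-percentile calibration threshold must not exceed E;
3. **complexity** — among survivors, minimum AICc computed from the
   raw-scale likelihood with k = number of non-zero feature weights.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .maxent import MaxentNiche, MaxentResults
from .transfer import e_threshold

__all__ = [
    "EvalParams",
    "omission_rate",
    "partial_roc",
    "aicc",
    "calibrate_candidates",
    "select_best",
    "SelectionReport",
]


@dataclasses.dataclass
class EvalParams:
    """Evaluation settings: E = acceptable omission error, pROC bootstrap
    iterations and resample fraction, significance level alpha."""

    E: float = 0.05
    proc_iterations: int = 500
    proc_resample: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.E < 1:
            raise ValueError("E must be in (0, 1)")
        if self.proc_iterations < 100:
            raise ValueError("need at least 100 pROC iterations")
        if not 0 < self.proc_resample <= 1:
            raise ValueError("resample fraction must be in (0, 1]")


def omission_rate(
    pred_values: np.ndarray, threshold: float
) -> float:
    """Fraction of evaluation points predicted below ``threshold``.

    ``pred_values`` are the model predictions at the evaluation points
    (points falling on no-data cells must be excluded upstream; see
    :func:`predicted_at_points`).
    """
    vals = np.asarray(pred_values, float)
    if vals.size == 0:
        raise ValueError("no evaluation points")
    return float((vals < threshold).mean())


def predicted_at_points(
    raster: np.ndarray, grid, lonlat: np.ndarray
) -> np.ndarray:
    """Raster values at point locations; off-grid / no-data points are
    dropped with a warning stating how many."""
    vals = []
    dropped = 0
    for lon, lat in np.asarray(lonlat, float):
        try:
            r, c = grid.cell_of(lon, lat)
        except ValueError:
            dropped += 1
            continue
        v = raster[r, c]
        if np.isnan(v):
            dropped += 1
        else:
            vals.append(v)
    if dropped:
        warnings.warn(f"{dropped} evaluation point(s) off-grid or on no-data cells")
    return np.asarray(vals)


def partial_roc(
    cell_values: np.ndarray,
    eval_values: np.ndarray,
    E: float = 0.05,
    iterations: int = 500,
    resample_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[float, float]:
    """Partial-ROC significance test.

    Per bootstrap iteration, ``ceil(resample_fraction * n)`` evaluation
    points are resampled with replacement and the partial AUC of the
    model curve (sensitivity vs proportional predicted area) above
    sensitivity ``1 - E`` is divided by the partial AUC of the uniform
    random-prediction line over the same area range.  Returns
    ``(mean AUC ratio, p)`` with ``p`` the fraction of iterations whose
    ratio is <= 1.  A spatially constant prediction makes the ratio
    undefined; it is reported as (1.0, 1.0) with a warning.
    """
    cell_values = np.asarray(cell_values, float)
    cell_values = cell_values[np.isfinite(cell_values)]
    eval_values = np.asarray(eval_values, float)
    n = eval_values.size
    if n < 10:
        raise ValueError("need at least 10 evaluation points for partial ROC")
    if np.ptp(cell_values) == 0:
        warnings.warn("constant prediction surface: partial ROC undefined")
        return 1.0, 1.0
    # threshold grid over the prediction's value range
    if np.unique(cell_values).size <= 512:
        thresholds = np.unique(cell_values)
    else:
        thresholds = np.unique(np.quantile(cell_values, np.linspace(0, 1, 512)))
    # x(t): fraction of cells with value >= t (proportional predicted area)
    cs = np.sort(cell_values)
    area = 1.0 - np.searchsorted(cs, thresholds, side="left") / cs.size
    rng = np.random.default_rng(seed)
    m = int(np.ceil(resample_fraction * n))
    # integration region fixed by the full evaluation sample: thresholds at
    # which its sensitivity stays >= 1 - E.  Deriving the region per
    # bootstrap iteration instead would select on the resampled curve's own
    # noise and inflate the type-I error of the test.
    ev_sorted = np.sort(eval_values)
    sens_full = 1.0 - np.searchsorted(ev_sorted, thresholds, side="left") / n
    keep = sens_full >= 1.0 - E
    if not keep.any():
        keep = thresholds == thresholds[0]
    ratios = np.empty(iterations)
    for it in range(iterations):
        sample = eval_values[rng.integers(0, n, size=m)]
        ssort = np.sort(sample)
        sens = 1.0 - np.searchsorted(ssort, thresholds, side="left") / m
        ratios[it] = _pauc_ratio(area[keep], sens[keep])
    mean_ratio = float(np.mean(ratios))
    p = float(np.mean(ratios <= 1.0))
    return mean_ratio, p


def _pauc_ratio(area: np.ndarray, sens: np.ndarray) -> float:
    """Ratio of model to random partial AUC over a fixed area range.

    ``area`` and ``sens`` are evaluated on a shared ascending threshold
    grid restricted to the high-sensitivity region, so both decrease
    with index.  The random-expectation curve is sensitivity = area,
    whose partial integral over [x0, x1] is (x1^2 - x0^2) / 2.
    """
    x = area[::-1]          # ascending area
    y = sens[::-1]
    # extend to the full-area corner of the ROC space
    if x[-1] < 1.0:
        x = np.append(x, 1.0)
        y = np.append(y, 1.0)
    pauc_model = np.trapezoid(y, x)
    pauc_random = (x[-1] ** 2 - x[0] ** 2) / 2.0
    if pauc_random <= 0:
        return 1.0
    return float(pauc_model / pauc_random)


def aicc(lnL: float, k: int, n: int) -> tuple[float, bool]:
    """Small-sample corrected Akaike information criterion.

    ``AICc = 2k - 2 lnL + 2k(k+1)/(n-k-1)``; when ``k >= n - 1`` the
    correction blows up and the value is reported as +inf with a flag.
    """
    if k >= n - 1:
        return float("inf"), True
    if not np.isfinite(lnL):
        return float("inf"), True
    return 2.0 * k - 2.0 * lnL + 2.0 * k * (k + 1) / (n - k - 1), False


def aicc_from_results(
    res: MaxentResults, calib_env: np.ndarray
) -> tuple[float, bool]:
    """AICc of a fitted model from raw predictions at calibration points.

    The raw output is already normalized over the training background,
    so ``lnL = sum_i log raw(x_i)``; a zero raw value at any occurrence
    gives lnL = -inf and a flagged +inf AICc.
    """
    raw = res.predict(calib_env, scale="raw")
    n = calib_env.shape[0]
    k = res.count_parameters()
    with np.errstate(divide="ignore"):
        lnL = float(np.sum(np.log(raw)))
    return aicc(lnL, k, n)


@dataclasses.dataclass
class SelectionReport:
    """Outcome of the three-stage selection rule."""

    total: int
    significant: int
    performant: int
    selected_id: str
    delta_aicc_runner_up: float
    relaxed: bool = False

    def __post_init__(self) -> None:
        assert 1 <= self.performant or self.relaxed
        assert self.performant <= self.significant <= self.total


def calibrate_candidates(
    stack,
    calib_lonlat: np.ndarray,
    eval_lonlat: np.ndarray,
    variable_sets: Sequence[Sequence[str]],
    class_subsets: Sequence[str],
    rms: Sequence[float],
    params: EvalParams | None = None,
    seed: int = 0,
    knots: int = 9,
    max_background: int = 10_000,
) -> pd.DataFrame:
    """Fit and evaluate the full candidate grid.

    One row per (variable set, feature classes, RM): partial-ROC mean
    AUC ratio and p, omission rate at the E-percentile calibration
    threshold, AICc and k, plus significance/performance flags.
    Failures are recorded in the ``error`` column, never dropped
    silently.  Deterministic under a fixed seed.
    """
    params = params or EvalParams()
    if not (len(variable_sets) and len(class_subsets) and len(rms)):
        raise ValueError("empty candidate grid")
    rows = []
    n_fail = 0
    for si, vset in enumerate(variable_sets):
        sub = stack.subset(vset)
        for classes in class_subsets:
            for rm in rms:
                cid = f"set{si:03d}_{classes}_rm{rm:g}"
                rec = {
                    "id": cid,
                    "variables": ",".join(vset),
                    "classes": classes,
                    "rm": rm,
                    "auc_ratio": np.nan,
                    "p_value": np.nan,
                    "omission": np.nan,
                    "aicc": np.nan,
                    "k": -1,
                    "significant": False,
                    "performant": False,
                    "error": "",
                }
                try:
                    model = MaxentNiche.from_stack(
                        sub, calib_lonlat, classes=classes, knots=knots,
                        max_background=max_background, seed=seed,
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = model.fit(rm=rm)
                    pred = res.predict(sub, scale="cloglog")
                    calib_vals = predicted_at_points(pred, sub.grid, calib_lonlat)
                    eval_vals = predicted_at_points(pred, sub.grid, eval_lonlat)
                    thr = e_threshold(calib_vals, params.E)
                    om = omission_rate(eval_vals, thr)
                    cell_vals = pred[sub.mask]
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        ratio, p = partial_roc(
                            cell_vals, eval_vals, params.E,
                            params.proc_iterations, params.proc_resample,
                            seed=seed + 17 * si,
                        )
                    ai, flagged = aicc_from_results(
                        res, _env_at(sub, calib_lonlat)
                    )
                    rec.update(
                        auc_ratio=ratio, p_value=p, omission=om,
                        aicc=ai, k=res.count_parameters(),
                        significant=bool(p < params.alpha),
                        performant=bool(p < params.alpha and om <= params.E),
                    )
                except Exception as exc:  # recorded, not dropped
                    rec["error"] = f"{type(exc).__name__}: {exc}"
                    n_fail += 1
                rows.append(rec)
    if n_fail == len(rows):
        raise RuntimeError("every candidate model failed")
    return pd.DataFrame(rows)


def _env_at(stack, lonlat: np.ndarray) -> np.ndarray:
    rc = np.array([stack.grid.cell_of(lon, lat) for lon, lat in np.asarray(lonlat)])
    return stack.values_at(rc[:, 0], rc[:, 1])


def select_best(
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    E: float = 0.05,
) -> SelectionReport:
    """Three-stage best-model choice over a candidate table.

    Significance (p < alpha), then performance (omission <= E), then
    minimum AICc; AICc ties broken by smaller k, then fewer variables,
    then lexicographic id.  If every significant candidate fails the
    omission filter, the minimum-omission candidates are used instead
    and the report is marked ``relaxed``.
    """
    if candidates.empty:
        raise ValueError("no candidates")
    ok = candidates[candidates["error"] == ""]
    sig = ok[ok["p_value"] < alpha]
    if sig.empty:
        raise ValueError(
            "no candidate is statistically significant; expand the candidate grid"
        )
    perf = sig[sig["omission"] <= E]
    relaxed = False
    if perf.empty:
        relaxed = True
        perf = sig[sig["omission"] == sig["omission"].min()]
        warnings.warn(
            "no candidate met the omission criterion; falling back to "
            "minimum-omission candidates (report marked 'relaxed')"
        )
    perf = perf.assign(_nvars=perf["variables"].str.count(",") + 1)
    ordered = perf.sort_values(
        ["aicc", "k", "_nvars", "id"], kind="mergesort"
    )
    best = ordered.iloc[0]
    delta = float(ordered.iloc[1]["aicc"] - best["aicc"]) if len(ordered) > 1 else float("inf")
    return SelectionReport(
        total=len(candidates),
        significant=len(sig),
        performant=len(perf) if not relaxed else 0,
        selected_id=str(best["id"]),
        delta_aicc_runner_up=delta,
        relaxed=relaxed,
    )
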