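"""End-to-end pipeline: simulate -> thin/split -> filter -> calibrate ->
select -> bootstrap-median transfer -> MOP -> binarize -> ensemble ->
exposure, driven by one config, with a machine-readable run manifest.

Every stage is a pure function of (inputs, config, seed); the single
global seed is expanded into per-stage seeds by a fixed counter scheme
(``stage_seed``), so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import envlayers, exposure as exposure_mod, synthetic, transfer
from .grids import Grid, write_ascii_grid
from .occurrences import (
    build_accessible_area,
    load_occurrences,
    split_calibration,
    thin,
)
from .selection import EvalParams, calibrate_candidates, select_best

__all__ = ["RunConfig", "run_all", "stage_seed"]

_STAGES = [
    "simulate",
    "thin",
    "split",
    "area",
    "filter",
    "calibrate",
    "select",
    "transfer",
    "mop",
    "ensemble",
    "exposure",
]


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed: global seed advanced by a fixed per-stage counter."""
    return (seed + 99991 * (_STAGES.index(stage) + 1)) % (2**31)


@dataclasses.dataclass
class RunConfig:
    """Every numeric setting of the workflow, with documented defaults.

    Defaults mirror the standard protocol for this analysis: 22 km
    thinning, 50/50 calibration split, 200 km accessible-area buffer,
    |r| < 0.80 collinearity filter, E = 0.05, alpha = 0.05, 10 bootstrap
    replicates, >= 60% ensemble agreement.
    """

    output_dir: str = "vectorenm_out"
    seed: int = 0
    # synthetic world
    nrows: int = 60
    ncols: int = 60
    cellsize: float = 0.2
    xll: float = -100.0
    yll: float = 10.0
    n_layers: int = 7
    correlation: float = 0.3
    smooth_sigma: float = 3.0
    n_gcm: int = 5
    gcm_noise_sd: float = 0.3
    n_occurrences: int = 400
    n_regions: int = 3
    # occurrence prep
    thin_km: float = 22.0
    thin_restarts: int = 100
    split_fraction: float = 0.5
    buffer_km: float = 200.0
    # variables
    r_max: float = 0.80
    min_set_size: int = 2
    candidate_sets: Sequence[Sequence[str]] | str = "all"
    max_candidate_sets: int = 10
    class_subsets: Sequence[str] = ("lq",)
    rms: Sequence[float] = (0.5, 1.0, 2.0)
    knots: int = 9
    # evaluation / selection
    E: float = 0.05
    alpha: float = 0.05
    proc_iterations: int = 200
    proc_resample: float = 0.5
    # transfer
    n_boot: int = 10
    cutoff_frac: float = 0.6
    mop_reference_fraction: float = 0.1
    mop_sample_cap: int = 5000
    max_background: int = 10_000
    # exposure
    breakpoints: Sequence[float] = exposure_mod.DEFAULT_BREAKPOINTS
    strong_only: bool = True
    flag_cutoff: float = 10.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        """Raise with *every* violation listed, not only the first."""
        errs = []
        if not 0 < self.E < 1:
            errs.append(f"E must be in (0, 1), got {self.E}")
        if not 0 < self.alpha < 1:
            errs.append(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.split_fraction < 1:
            errs.append(f"split_fraction must be in (0, 1), got {self.split_fraction}")
        if self.thin_km <= 0:
            errs.append(f"thin_km must be positive, got {self.thin_km}")
        if self.buffer_km < 0:
            errs.append(f"buffer_km must be >= 0, got {self.buffer_km}")
        if not 0 < self.r_max <= 1:
            errs.append(f"r_max must be in (0, 1], got {self.r_max}")
        if self.n_boot < 1:
            errs.append(f"n_boot must be >= 1, got {self.n_boot}")
        if not 0 < self.cutoff_frac <= 1:
            errs.append(f"cutoff_frac must be in (0, 1], got {self.cutoff_frac}")
        if not 0 < self.mop_reference_fraction <= 1:
            errs.append(
                f"mop_reference_fraction must be in (0, 1], got {self.mop_reference_fraction}"
            )
        if self.min_set_size < 2:
            errs.append(f"min_set_size must be >= 2, got {self.min_set_size}")
        bp = list(self.breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp[:-1], bp[1:])):
            errs.append("breakpoints must be strictly increasing")
        if errs:
            raise ValueError("invalid config:\n  " + "\n  ".join(errs))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["candidate_sets"] = (
            self.candidate_sets
            if isinstance(self.candidate_sets, str)
            else [list(s) for s in self.candidate_sets]
        )
        d["class_subsets"] = list(self.class_subsets)
        d["rms"] = list(self.rms)
        d["breakpoints"] = list(self.breakpoints)
        return d

    @classmethod
    def demo(cls, output_dir: str = "vectorenm_demo", seed: int = 1) -> "RunConfig":
        """Small self-contained configuration that exercises every stage."""
        return cls(
            output_dir=output_dir,
            seed=seed,
            nrows=50,
            ncols=50,
            n_gcm=5,
            n_occurrences=250,
            thin_restarts=10,
            candidate_sets=[
                ["bio1", "bio4", "bio12", "bio14", "rh"],
                ["bio1", "bio4", "bio6"],
                ["bio6", "bio15"],
            ],
            class_subsets=("lq",),
            rms=(1.0,),
            proc_iterations=200,
            n_boot=5,
            mop_sample_cap=1500,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every stage in dependency order; return the run manifest.

    Any stage failure halts with a stage-tagged error; outputs written
    before the failure are preserved in the output directory.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "warnings": [],
    }

    caught: list[str] = []

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.time()
                self_inner.wm = warnings.catch_warnings(record=True)
                self_inner.records = self_inner.wm.__enter__()
                warnings.simplefilter("always")
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                self_inner.wm.__exit__(None, None, None)
                for w in self_inner.records:
                    caught.append(f"{name}: {w.message}")
                manifest["stages"].setdefault(name, {})["seconds"] = round(
                    time.time() - self_inner.t0, 3
                )
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return _Ctx()

    def _record(stage: str, *paths: Path) -> None:
        st = manifest["stages"].setdefault(stage, {})
        st.setdefault("outputs", {})
        for p in paths:
            st["outputs"][p.name] = _sha256(p)

    grid = Grid(config.nrows, config.ncols, config.cellsize, config.xll, config.yll)
    spec = synthetic.SyntheticSpec(
        grid=grid,
        n_layers=config.n_layers,
        correlation=config.correlation,
        n_gcm=config.n_gcm,
        gcm_noise_sd=config.gcm_noise_sd,
        smooth_sigma=config.smooth_sigma,
        seed=stage_seed(config.seed, "simulate"),
    )

    with _stage("simulate"):
        stack = synthetic.gen_env_stack(spec)
        truth = synthetic.make_truth(stack, spec)
        occ_raw = synthetic.sample_occurrences(
            truth, config.n_occurrences, seed=stage_seed(config.seed, "simulate") + 1
        )
        futures = synthetic.gen_future_stacks(stack, spec)
        cattle, regions = synthetic.gen_cattle_and_regions(spec, config.n_regions)
        occ_path = out / "occurrences_raw.csv"
        occ_raw.to_csv(occ_path, index=False)
        write_ascii_grid(out / "truth_suitability.asc", truth.suitability, grid)
        write_ascii_grid(out / "cattle.asc", cattle, grid)
        write_ascii_grid(out / "regions.asc", regions.astype(float), grid)
        _record("simulate", occ_path, out / "truth_suitability.asc",
                out / "cattle.asc", out / "regions.asc")

    with _stage("thin"):
        occ = load_occurrences(occ_raw)
        occ_thin = thin(
            occ, config.thin_km,
            seed=stage_seed(config.seed, "thin"),
            restarts=config.thin_restarts,
        )
        p = out / "occurrences_thinned.csv"
        occ_thin.to_csv(p, index=False)
        _record("thin", p)

    with _stage("split"):
        cal, ev = split_calibration(
            occ_thin, config.split_fraction, seed=stage_seed(config.seed, "split")
        )
        p = out / "occurrences_split.csv"
        pd.concat([cal, ev]).to_csv(p, index=False)
        _record("split", p)

    with _stage("area"):
        area = build_accessible_area(cal, config.buffer_km, grid)
        p = out / "accessible_area.asc"
        write_ascii_grid(p, area.mask.astype(float), grid)
        _record("area", p)
        cal_stack = envlayers.crop_stack(stack, area)

    with _stage("filter"):
        retained = envlayers.pearson_filter(cal_stack, config.r_max)
        p = out / "retained_variables.txt"
        p.write_text("\n".join(retained) + "\n")
        _record("filter", p)
        if config.candidate_sets == "all":
            sets = envlayers.enumerate_variable_sets(retained, config.min_set_size)
            sets = [list(s) for s in sets[: config.max_candidate_sets]]
        else:
            sets = [[v for v in s if v in retained] for s in config.candidate_sets]
            sets = [s for s in sets if len(s) >= config.min_set_size]
            if not sets:
                raise ValueError("no candidate variable set survives filtering")

    cal_xy = cal[["longitude", "latitude"]].to_numpy()
    ev_xy = ev[["longitude", "latitude"]].to_numpy()
    eval_params = EvalParams(
        E=config.E,
        proc_iterations=config.proc_iterations,
        proc_resample=config.proc_resample,
        alpha=config.alpha,
    )

    with _stage("calibrate"):
        candidates = calibrate_candidates(
            cal_stack, cal_xy, ev_xy,
            sets, list(config.class_subsets), list(config.rms),
            params=eval_params,
            seed=stage_seed(config.seed, "calibrate"),
            knots=config.knots,
            max_background=config.max_background,
        )
        p = out / "candidates.csv"
        candidates.to_csv(p, index=False)
        _record("calibrate", p)

    with _stage("select"):
        report = select_best(candidates, config.alpha, config.E)
        best = candidates.set_index("id").loc[report.selected_id]
        sel = dataclasses.asdict(report)
        sel["best"] = {
            "variables": best["variables"],
            "classes": best["classes"],
            "rm": float(best["rm"]),
            "aicc": float(best["aicc"]),
            "omission": float(best["omission"]),
            "p_value": float(best["p_value"]),
        }
        p = out / "selection.json"
        p.write_text(json.dumps(sel, indent=1))
        _record("select", p)

    best_vars = best["variables"].split(",")
    best_stack = cal_stack.subset(best_vars)

    with _stage("transfer"):
        targets: dict[Any, Any] = {"present": stack.subset(best_vars)}
        for key, fut in futures.items():
            targets[key] = fut.subset(best_vars)
        projections = transfer.bootstrap_median_model(
            best_stack, cal_xy, targets,
            classes=best["classes"], rm=float(best["rm"]),
            knots=config.knots, n_boot=config.n_boot,
            seed=stage_seed(config.seed, "transfer"),
            max_background=config.max_background,
        )
        p = out / "present_suitability.asc"
        write_ascii_grid(p, projections["present"], grid)
        _record("transfer", p)

    scen_keys = sorted({(k[1], k[2]) for k in futures})

    with _stage("mop"):
        mop_paths = []
        for rcp, period in scen_keys:
            gcm_keys = [k for k in futures if k[1] == rcp and k[2] == period]
            mean_layers = {
                v: np.mean([futures[k][v] for k in gcm_keys], axis=0)
                for v in best_vars
            }
            from .grids import LayerStack

            mean_stack = LayerStack(grid, mean_layers, stack.mask)
            surf = transfer.mop(
                best_stack, mean_stack,
                config.mop_reference_fraction, config.mop_sample_cap,
                seed=stage_seed(config.seed, "mop"),
            )
            mp = out / f"mop_similarity_{rcp}_{period}.asc"
            write_ascii_grid(mp, surf.similarity, grid)
            sp = out / f"mop_strict_{rcp}_{period}.asc"
            write_ascii_grid(sp, surf.strict_extrapolation.astype(float), grid)
            mop_paths += [mp, sp]
        _record("mop", *mop_paths)

    with _stage("ensemble"):
        # common threshold from present-day calibration suitabilities
        from .selection import predicted_at_points

        calib_vals = predicted_at_points(projections["present"], grid, cal_xy)
        present_binary, threshold = transfer.binarize(
            projections["present"], calib_vals, config.E
        )
        write_ascii_grid(out / "present_binary.asc", present_binary.astype(float), grid)
        change_paths = [out / "present_binary.asc"]
        change_maps: dict[tuple[str, str], np.ndarray] = {}
        for rcp, period in scen_keys:
            gcm_keys = [k for k in futures if k[1] == rcp and k[2] == period]
            binaries = [projections[k] >= threshold for k in gcm_keys]
            agr = transfer.agreement(binaries, config.cutoff_frac)
            change = transfer.classify_change(present_binary, agr)
            change_maps[(rcp, period)] = change
            cp = out / f"change_{rcp}_{period}.asc"
            write_ascii_grid(cp, change.astype(float), grid)
            ap = out / f"agreement_{rcp}_{period}.asc"
            write_ascii_grid(ap, agr.counts.astype(float), grid)
            change_paths += [cp, ap]
        manifest["binarization_threshold"] = float(threshold)
        _record("ensemble", *change_paths)

    with _stage("exposure"):
        cats = exposure_mod.categorize_cattle(cattle, config.breakpoints)
        table_paths = []
        for period in sorted({p_ for _, p_ in scen_keys}):
            per_scen = {
                rcp: change_maps[(rcp, p_)]
                for rcp, p_ in scen_keys
                if p_ == period
            }
            tbl = exposure_mod.exposure_table(
                present_binary, per_scen, cats, regions,
                strong_only=config.strong_only,
            )
            flags = exposure_mod.flag_high(tbl, config.flag_cutoff)
            tp = out / f"exposure_{period}.csv"
            fp = out / f"exposure_{period}_flags.csv"
            tbl.to_csv(tp, index=False)
            flags.to_csv(fp, index=False)
            table_paths += [tp, fp]
        _record("exposure", *table_paths)

    manifest["warnings"] = caught
    manifest["selection"] = sel
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
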