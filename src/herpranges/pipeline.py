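"""End-to-end experiment: simulate -> thin -> estimate -> score -> summarize.

One config drives the whole study.  For every individual x regime x
method the pipeline records either a scored row (confusion areas,
commission/omission %, precision/recall/F) or a failure row with a
status string — rows are never dropped silently.  The per-individual
evaluation grid (resolution = species buffer width / 4) is shared by
every method so overlap arithmetic is comparable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import dbbmm as _dbbmm
from .estimators import (
    DegenerateGeometryError,
    ParameterError as _EstParamError,
    href_bandwidth,
    kde_ud,
    lscv_bandwidth,
    mcp_region,
)
from .grids import GridError, isopleth_region, make_grid
from .landscape import generate_fbm_landscape
from .metrics import score_region, true_pathway_buffer
from .movement import Trajectory, archetype_presets, simulate_population
from .regimes import apply_regime, regime_schedule

__all__ = ["ExperimentConfig", "run_experiment", "summarize", "compare_regime8"]

log = logging.getLogger("herpranges")

ALL_METHODS = ("MCP", "KDE_href", "KDE_LSCV", "dBBMM")


@dataclass
class ExperimentConfig:
    seed: int
    n_per_species: int = 3
    duration_days: int = 365
    dt: float = 1800.0
    regimes: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    methods: tuple[str, ...] = ALL_METHODS
    level: float = 0.95
    landscape_shape: tuple[int, int] = (512, 512)
    landscape_cell: float = 10.0
    landscape_hurst: float = 0.5
    dbbmm_window: int = 31
    dbbmm_margin: int = 11
    loc_error: float = 5.0
    time_substeps: int = 10
    grid_res_divisor: float = 4.0  # cell size = buffer_width / divisor
    lscv_max_n: int | None = 4000  # guard against O(n^2) blow-up; None = no cap
    species: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if not set(self.regimes) <= set(range(1, 9)):
            raise ValueError("regimes must be a subset of 1..8")
        if not set(self.methods) <= set(ALL_METHODS):
            raise ValueError(f"methods must be a subset of {ALL_METHODS}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("regimes", "methods", "landscape_shape", "species"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha1(repr(sorted(asdict(self).items())).encode()).hexdigest()[:12]


def _failure_row(base: dict, method: str, status: str) -> dict:
    row = dict(base)
    row.update(method=method, status=status, converged=False)
    return row


def _evaluate_individual(
    traj: Trajectory,
    config: ExperimentConfig,
    rows: list[dict],
) -> None:
    params = archetype_presets(traj.species_id)
    buffer_w = params.buffer_width
    regimes = list(config.regimes)
    thinned: dict[int, Trajectory] = {}
    for r in regimes:
        thinned[r] = apply_regime(traj, regime_schedule(r))

    # bandwidths and motion-variance series first: the shared grid padding
    # must cover every kernel and every bridge
    bandwidths: dict[tuple[int, str], object] = {}
    mvseries: dict[int, _dbbmm.MotionVarianceSeries] = {}
    pads = [3.0 * buffer_w]
    for r in regimes:
        sub = thinned[r]
        pts = np.column_stack([sub.x, sub.y])
        if "KDE_href" in config.methods or "KDE_LSCV" in config.methods:
            try:
                bw = href_bandwidth(pts)
                bandwidths[(r, "KDE_href")] = bw
                pads.append(3.0 * bw.h)
            except _EstParamError as exc:
                bandwidths[(r, "KDE_href")] = str(exc)
        if "KDE_LSCV" in config.methods:
            if sub.n_fixes < 10:
                bandwidths[(r, "KDE_LSCV")] = "too_few_fixes_for_LSCV"
            elif config.lscv_max_n is not None and sub.n_fixes > config.lscv_max_n:
                bandwidths[(r, "KDE_LSCV")] = "skipped_n_above_lscv_cap"
            elif isinstance(bandwidths.get((r, "KDE_href")), str):
                bandwidths[(r, "KDE_LSCV")] = "zero_variance_input"
            else:
                bw = lscv_bandwidth(pts)
                bandwidths[(r, "KDE_LSCV")] = bw
                pads.append(3.0 * bw.h)
        if "dBBMM" in config.methods and sub.n_fixes >= 3:
            mvs = _dbbmm.dynamic_variance_series(
                sub,
                window_size=config.dbbmm_window,
                margin=config.dbbmm_margin,
                delta=config.loc_error,
            )
            mvseries[r] = mvs
            pads.append(5.0 * _dbbmm.max_bridge_sd(sub, mvs))

    grid = make_grid(
        traj.x, traj.y, cell_size=buffer_w / config.grid_res_divisor, padding=max(pads)
    )
    truth = true_pathway_buffer(traj, buffer_w, grid)

    for r in regimes:
        sub = thinned[r]
        pts = np.column_stack([sub.x, sub.y])
        base = dict(
            species=traj.species_id,
            individual_id=traj.individual_id,
            regime=r,
            n_fixes=sub.n_fixes,
            truth_area_m2=truth.area,
        )
        for method in config.methods:
            try:
                h = np.nan
                sigma2_mean = np.nan
                converged = True
                if method == "MCP":
                    region = mcp_region(pts, level=config.level)
                elif method in ("KDE_href", "KDE_LSCV"):
                    bw = bandwidths.get((r, method))
                    if isinstance(bw, str):
                        rows.append(_failure_row(base, method, bw))
                        continue
                    h = bw.h
                    converged = bw.converged
                    ud = kde_ud(pts, bw.h, grid)
                    region = isopleth_region(ud, config.level, method)
                    region.converged = converged
                elif method == "dBBMM":
                    if r not in mvseries:
                        rows.append(_failure_row(base, method, "too_few_fixes_for_dBBMM"))
                        continue
                    mvs = mvseries[r]
                    sigma2_mean = float(np.mean(mvs.sigma2m))
                    ud = _dbbmm.dbbmm_ud(sub, mvs, grid, time_substeps=config.time_substeps)
                    region = isopleth_region(ud, config.level, method)
                m = score_region(region, truth)
                row = dict(base)
                row.update(
                    method=method,
                    status="ok",
                    converged=converged,
                    h=h,
                    sigma2m_mean=sigma2_mean,
                    area_m2=region.rasterize(grid).area if region.mask is None else region.area,
                    tp_m2=m.tp_area,
                    fp_m2=m.fp_area,
                    fn_m2=m.fn_area,
                    commission_pct=m.commission_pct,
                    omission_pct=m.omission_pct,
                    precision=m.precision,
                    recall=m.recall,
                    f_measure=m.f_measure,
                )
                rows.append(row)
            except (DegenerateGeometryError, GridError, _EstParamError, ValueError) as exc:
                log.warning("%s regime %s %s failed: %s", traj.individual_id, r, method, exc)
                rows.append(_failure_row(base, method, f"error: {exc}"))


def run_experiment(
    config: ExperimentConfig,
    trajectories: list[Trajectory] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full sweep; returns (tidy results table, manifest).

    If ``trajectories`` is given they are used instead of simulating (they
    must be full-resolution tracks aligned to the study clock).
    """
    if trajectories is None:
        land = generate_fbm_landscape(
            config.landscape_shape[0],
            config.landscape_shape[1],
            config.landscape_cell,
            hurst=config.landscape_hurst,
            seed=config.seed,
        )
        trajectories = simulate_population(
            land,
            n_per_species=config.n_per_species,
            seed=config.seed,
            duration_days=config.duration_days,
            dt=config.dt,
        )
        trajectories = [tr for tr in trajectories if tr.species_id in config.species]

    rows: list[dict] = []
    for traj in trajectories:
        _evaluate_individual(traj, config, rows)

    results = pd.DataFrame(rows)
    n_failures = int((results["status"] != "ok").sum()) if len(results) else 0
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_individuals": len(trajectories),
        "n_rows": len(results),
        "n_failures": n_failures,
    }
    return results, manifest


def lscv_failure_study(
    seed: int,
    n_per_species: int = 3,
    landscape_shape: tuple[int, int] = (512, 512),
) -> pd.DataFrame:
    """LSCV convergence on high-frequency thinnings (regimes 1-4).

    Regimes 1 and 2 use two-month tracks to bound the O(n^2) score cost;
    regimes 3 and 4 use full-year tracks.  Returns one row per fit with
    the boundary-minimum convergence flag.
    """
    land = generate_fbm_landscape(
        landscape_shape[0], landscape_shape[1], 10.0, hurst=0.5, seed=seed
    )
    rows = []
    for duration, regimes in ((60, (1, 2)), (365, (3, 4))):
        pop = simulate_population(
            land, n_per_species=n_per_species, seed=seed + duration, duration_days=duration
        )
        for traj in pop:
            for r in regimes:
                sub = apply_regime(traj, regime_schedule(r))
                bw = lscv_bandwidth(np.column_stack([sub.x, sub.y]))
                rows.append(
                    dict(
                        species=traj.species_id,
                        individual_id=traj.individual_id,
                        regime=r,
                        duration_days=duration,
                        n_fixes=sub.n_fixes,
                        h=bw.h,
                        converged=bw.converged,
                    )
                )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Mean +/- SE summaries and the LSCV failure proportion per regime."""
    if len(results) == 0:
        raise ValueError("empty results")
    ok = results[results["status"] == "ok"]
    metrics = ["commission_pct", "omission_pct", "f_measure"]

    def _agg(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        g = df.groupby(keys)[metrics]
        mean = g.mean().add_suffix("_mean")
        se = (g.std(ddof=1) / np.sqrt(g.count().clip(lower=1))).add_suffix("_se")
        out = mean.join(se.fillna(0.0)).reset_index()
        out["n"] = g.size().to_numpy()
        return out

    pooled = _agg(ok, ["method", "regime"])
    by_species = _agg(ok, ["species", "method", "regime"])

    lscv = results[results["method"] == "KDE_LSCV"]
    attempted = lscv[~lscv["status"].str.startswith("skipped", na=False)]
    fail = (
        attempted.assign(failed=lambda d: (d["status"] != "ok") | (~d["converged"].astype(bool)))
        .groupby("regime")["failed"]
        .mean()
        .mul(100.0)
        .rename("lscv_failure_pct")
        .reset_index()
        if len(attempted)
        else pd.DataFrame(columns=["regime", "lscv_failure_pct"])
    )
    return {"pooled": pooled, "by_species": by_species, "lscv_failure": fail}


def compare_regime8(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Paired regime-8 minus regime-2 differences for KDE LSCV and dBBMM."""
    need = {2, 8}
    have = set(results["regime"].unique())
    if not need <= have:
        raise ValueError("results must contain regimes 2 and 8")
    ok = results[(results["status"] == "ok") & results["method"].isin(["KDE_LSCV", "dBBMM"])]
    metrics = ["commission_pct", "omission_pct", "f_measure"]
    r2 = ok[ok["regime"] == 2].set_index(["method", "individual_id"])
    r8 = ok[ok["regime"] == 8].set_index(["method", "individual_id"])
    common = r2.index.intersection(r8.index)
    missing = sorted(set(r2.index.symmetric_difference(r8.index)))
    diffs = (r8.loc[common, metrics] - r2.loc[common, metrics]).reset_index()
    fixes = (
        results[results["regime"] == 8]
        .groupby("species")["n_fixes"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "n_fixes_mean", "std": "n_fixes_sd"})
    )
    return {
        "paired_diffs": diffs,
        "regime8_fix_counts": fixes,
        "missing_pairs": pd.DataFrame(missing, columns=["method", "individual_id"]),
    }
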