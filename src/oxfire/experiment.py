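"""The oxygen-sweep experiment and its diagnostics.

Runs the simulator once per atmospheric O2 level from present-day 20.95 %
vol. up to 35 % in 1 % steps, plus a no-fire baseline, every run against the
identical seeded weather stream; spins each run up to quasi-equilibrium and
averages the final decade.  Diagnostics follow the fire-window analysis:
global fire counts and burned area against O2, global tree and forest cover,
the forest-suppression metric (percentage decrease of forest area relative
to the fire-off world), and mean rate of spread per fuel-moisture band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig, WorldConfig
from .simulation import RunResult, run_simulation
from .world import DailyForcing

NO_FIRE = "no_fire"
BAND_LABELS = ("<20", "20-40", "40-60", ">60")


@dataclass
class ExperimentSummary:
    """Per-O2-level global diagnostics plus per-cell fields for every run."""

    summary: pd.DataFrame            # one row per level (+ the no-fire row)
    band_ros: pd.DataFrame           # moisture band x O2 level mean ros
    runs: dict[str, RunResult]       # keyed by formatted level or "no_fire"
    run_log: list[str] = field(default_factory=list)


def level_label(ox: float | None) -> str:
    return NO_FIRE if ox is None else f"{ox:g}"


def suppression_metric(forest_cover, forest_cover_no_fire: float):
    """Forest suppression, %: 100 * (1 - cover/cover_no_fire), floored at 0."""
    if forest_cover_no_fire <= 0.0:
        raise ValueError("no-fire forest cover is zero: suppression undefined")
    s = 100.0 * (1.0 - np.asarray(forest_cover, dtype=float) / forest_cover_no_fire)
    s = np.maximum(s, 0.0)
    return s if np.ndim(s) else float(s)


def assign_moisture_bands(mean_moisture: np.ndarray,
                          edges: tuple[float, ...]) -> np.ndarray:
    """Partition cells into moisture bands; returns integer band index."""
    return np.digitize(mean_moisture, bins=np.asarray(edges, dtype=float))


def moisture_band_analysis(
    reference: RunResult,
    runs: dict[str, RunResult],
    edges: tuple[float, ...],
) -> pd.DataFrame:
    """Mean rate of spread per fuel-moisture band per O2 level.

    Cells are binned once, by their 10-year-mean spread-relevant fuel
    moisture in the reference (present-day O2) run, so every level is
    tabulated over the same partition.  Empty bands are reported as NaN
    (missing), never as zero.
    """
    band = assign_moisture_bands(reference.mean_moisture, edges)
    labels = _band_labels(edges)
    out = {}
    for label, run in runs.items():
        if run.ox is None:
            continue
        col = []
        for b in range(len(labels)):
            mask = band == b
            col.append(float(run.mean_ros[mask].mean()) if mask.any() else np.nan)
        out[label] = col
    return pd.DataFrame(out, index=list(labels))


def _band_labels(edges: tuple[float, ...]) -> tuple[str, ...]:
    e = [f"{v:g}" for v in edges]
    inner = [f"{a}-{b}" for a, b in zip(e[:-1], e[1:])]
    return tuple([f"<{e[0]}"] + inner + [f">{e[-1]}"])


def relative_increase(first: float, last: float) -> float:
    """(last - first)/first with the 0/0 -> 0 convention (no change where
    nothing ever burns)."""
    if first == 0.0:
        return 0.0 if last == 0.0 else np.inf
    return (last - first) / first


def _globals(run: RunResult, model: ModelConfig) -> dict:
    w = run.cell_area_km2
    total = w.sum()
    thresh = model.vegetation.forest_threshold
    return {
        "fires_per_yr": float(run.fires_per_yr.sum()),
        "burned_area_km2_per_yr": float((run.burned_frac_per_yr * w).sum()),
        "burned_frac_per_yr": float((run.burned_frac_per_yr * w).sum() / total),
        "tree_cover": float((run.tree_cover * w).sum() / total),
        "forest_area_km2": run.forest_area_km2(thresh),
        "mean_ros": float((run.mean_ros * w).sum() / total),
    }


def run_experiment(
    world: WorldConfig,
    model: ModelConfig,
    seed: int,
    forcing: DailyForcing | None = None,
) -> ExperimentSummary:
    """Execute the full sweep plus (optionally) the no-fire baseline."""
    exp = model.experiment
    runs: dict[str, RunResult] = {}
    log: list[str] = []

    levels: list[float | None] = []
    if exp.no_fire_baseline:
        levels.append(None)
    levels.extend(exp.o2_levels)

    for ox in levels:
        res = run_simulation(
            world, model, ox, seed=seed, years=exp.spinup_years,
            record_years=exp.record_years, forcing=forcing,
        )
        runs[level_label(ox)] = res
        for line in res.log:
            log.append(f"[{level_label(ox)}] {line}")

    rows = []
    base_forest = (
        runs[NO_FIRE].forest_area_km2(model.vegetation.forest_threshold)
        if exp.no_fire_baseline else None
    )
    if base_forest == 0.0:
        log.append("no-fire world has no forest: suppression metric undefined")
    for ox in levels:
        label = level_label(ox)
        g = _globals(runs[label], model)
        g["level"] = label
        g["ox"] = np.nan if ox is None else float(ox)
        if base_forest is not None:
            g["suppression_pct"] = (
                suppression_metric(g["forest_area_km2"], base_forest)
                if base_forest > 0.0 else np.nan
            )
        rows.append(g)
    summary = pd.DataFrame(rows).set_index("level")

    pal_label = level_label(exp.o2_levels[0])
    band_ros = moisture_band_analysis(runs[pal_label], runs, exp.moisture_band_edges)
    return ExperimentSummary(summary=summary, band_ros=band_ros, runs=runs, run_log=log)


def write_outputs(result: ExperimentSummary, outdir: str | Path,
                  gridded: bool = True) -> None:
    """summary.csv, moisture-band table, run log, and per-level maps.

    Maps are written as NETCDF3 when the scipy backend is available,
    otherwise as long-format CSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(outdir / "summary.csv")
    result.band_ros.to_csv(outdir / "moisture_band_ros.csv", index_label="moisture_band")
    (outdir / "run_log.txt").write_text(
        "\n".join(result.run_log) + ("\n" if result.run_log else "")
    )
    if not gridded:
        return
    import xarray as xr

    for label, run in result.runs.items():
        ds = xr.Dataset(
            {
                "tree_cover": (("lat", "lon"), run.tree_cover),
                "mean_ros": (("lat", "lon"), run.mean_ros),
                "burned_frac_per_yr": (("lat", "lon"), run.burned_frac_per_yr),
                "fires_per_yr": (("lat", "lon"), run.fires_per_yr),
                "mean_fuel_moisture": (("lat", "lon"), run.mean_moisture),
            },
            coords={"lat": run.lat, "lon": run.lon},
        )
        try:
            ds.to_netcdf(outdir / f"maps_{label}.nc", engine="scipy")
        except (ImportError, ValueError):
            ds.to_dataframe().to_csv(outdir / f"maps_{label}.csv")
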