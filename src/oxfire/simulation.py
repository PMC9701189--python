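"""Daily fire-vegetation simulation over the synthetic grid.

Couples the three layers: the synthetic forcing stream drives fuel moisture
and fire danger; the fire engine converts lightning into expected ignitions,
spread, intensity and burned area; vegetation absorbs fire mortality daily
and regrows annually.  All oxygen dependence enters through the scaling
functions of :mod:`oxfire.oxygen`; with ``fire.oxygen_effects = False`` the
engine evaluates every scaling at present-day oxygen, which is the
regression baseline an ox = 20.95 run must reproduce bit for bit.

The state is held as whole-grid numpy arrays and the day loop is fully
vectorised over cells, which keeps multi-century spin-ups at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fire as fb
from . import oxygen as ox_mod
from . import vegetation as veg
from .config import ModelConfig, WorldConfig
from .fire import FuelBed
from .vegetation import ClimateSummary, GridCellState
from .world import DAYS, DailyForcing, ForcingGenerator, cell_areas_km2


@dataclass
class RunResult:
    """Ten-year-mean per-cell diagnostics plus run metadata."""

    ox: float | None                 # None for the no-fire run
    tree_cover: np.ndarray           # mean annual tree cover, (n_lat, n_lon)
    fires_per_yr: np.ndarray         # expected ignitions per cell-year
    burned_frac_per_yr: np.ndarray   # burned cell fraction per year
    mean_ros: np.ndarray             # unconditional daily-mean spread, m/min
    mean_moisture: np.ndarray        # mean spread-relevant fuel moisture, %
    annual_tree_cover: np.ndarray    # area-weighted global series, (years,)
    cell_area_km2: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    log: list[str] = field(default_factory=list)

    def forest_mask(self, threshold: float) -> np.ndarray:
        return self.tree_cover > threshold

    def forest_area_km2(self, threshold: float) -> float:
        return float(self.cell_area_km2[self.forest_mask(threshold)].sum())


def _initial_state(model: ModelConfig, shape: tuple[int, int]):
    n_pft = len(model.pfts)
    state = GridCellState(fpc=np.zeros((n_pft,) + shape))
    fuel = FuelBed(
        loads=np.zeros((len(model.fire.me_native),) + shape),
        moisture_fine=np.full(shape, 50.0),
        moisture_woody=np.full(shape, 50.0),
    )
    return state, fuel


def _annual_fuel_turnover(state: GridCellState, fuel: FuelBed, model: ModelConfig):
    """Litterfall in, decay out; standing live grass tracks grass cover."""
    cfg = model.vegetation
    tree = state.tree_cover(model.pfts)
    grass = state.grass_cover(model.pfts)
    split = np.asarray(cfg.tree_litter_split).reshape((-1, 1, 1))
    fuel.loads += cfg.tree_litter * tree[None] * split
    fuel.loads[0] += cfg.grass_litter * grass
    decay = np.asarray(cfg.fuel_decay).reshape((-1, 1, 1))
    fuel.loads *= 1.0 - decay
    fuel.loads[4] = cfg.grass_live_load * grass


def run_simulation(
    world: WorldConfig,
    model: ModelConfig,
    ox: float | None,
    seed: int,
    years: int,
    record_years: int = 10,
    forcing: DailyForcing | None = None,
) -> RunResult:
    """Spin up and record the final decade.

    ``ox = None`` disables the fire engine entirely (the no-fire baseline);
    otherwise ``ox`` is the % vol. O2 of the run.  When ``forcing`` is given
    its years are replayed cyclically instead of streaming from the seeded
    generator (used by the scripted fixtures).
    """
    fire_on = ox is not None
    fcfg, vcfg = model.fire, model.vegetation
    if fire_on:
        ox_eff = float(ox) if fcfg.oxygen_effects else ox_mod.OX_PAL
        h_pft = np.array(
            [ox_mod.pft_heat_of_combustion(ox_eff, p.alpha, p.beta) for p in model.pfts]
        )
        scaler = ox_mod.IgnitionScaler(ox_eff, pi_floor=fcfg.pi_floor)
        me_scaling = ox_mod.moisture_extinction_scaling(ox_eff)
        me_class_eff = fb.effective_extinction(ox_eff, fcfg.me_native, fcfg)

    shape = (world.n_lat, world.n_lon)
    area = cell_areas_km2(world)
    state, fuel = _initial_state(model, shape)
    nesterov = np.zeros(shape)
    climate: ClimateSummary | None = None

    is_grass = np.array([p.is_grass for p in model.pfts])
    ieff_base = np.array([p.ieff_base for p in model.pfts]).reshape((-1, 1, 1))
    susceptibility = np.array([p.susceptibility for p in model.pfts]).reshape((-1, 1, 1))
    kill_split = np.asarray(vcfg.kill_split).reshape((-1, 1, 1))

    gen = ForcingGenerator(world, seed) if forcing is None else None
    record_start = years - record_years
    burn_memory = np.zeros(shape)   # decaying burn-scar fraction for ieff_bf
    scar_decay = np.exp(-1.0 / fcfg.burn_scar_efolding_days)
    acc = {k: np.zeros(shape) for k in ("fires", "burned", "ros", "moisture", "cover")}
    annual_cover = np.zeros(years)
    weights = area / area.sum()
    log: list[str] = []

    for year in range(years):
        if gen is not None:
            f = gen.year()
            t_y, p_y, rh_y, wind_y, light_y = f.temp, f.precip, f.rh, f.wind, f.lightning
            lat, lon = f.lat, f.lon
        else:
            i0 = (year % (forcing.n_days // DAYS)) * DAYS
            sl = slice(i0, i0 + DAYS)
            t_y, p_y = forcing.temp[sl], forcing.precip[sl]
            rh_y, wind_y, light_y = forcing.rh[sl], forcing.wind[sl], forcing.lightning[sl]
            lat, lon = forcing.lat, forcing.lon

        this_year = veg.annual_climate(t_y, p_y)
        climate = this_year if climate is None else climate.blend(
            this_year, vcfg.climate_smoothing
        )

        cum_burned = np.zeros(shape)
        recording = year >= record_start
        cons_frac = np.asarray(fcfg.consumption).reshape((-1, 1, 1))
        for d in range(DAYS):
            m_eq = fb.equilibrium_moisture(rh_y[d], fcfg)
            fuel.moisture_fine = fb.relax_moisture(fuel.moisture_fine, m_eq, fcfg.tau_fine)
            fuel.moisture_woody = fb.relax_moisture(fuel.moisture_woody, m_eq, fcfg.tau_woody)
            nesterov = fb.nesterov_step(nesterov, t_y[d], p_y[d], rh_y[d], fcfg)
            if recording:
                bed = fb.bed_properties(fuel, fcfg)
                acc["moisture"] += np.where(
                    np.isfinite(bed.moisture), bed.moisture, fuel.moisture_fine
                )
            if not fire_on:
                continue
            if not recording:
                bed = fb.bed_properties(fuel, fcfg)

            fdi = fb.fdi_from_index(nesterov, fcfg)
            s_grass = scaler(fuel.moisture_fine)
            s_woody = scaler(fuel.moisture_woody)
            ieff_pft = ieff_base * np.where(
                is_grass.reshape((-1, 1, 1)), s_grass[None], s_woody[None]
            )
            fpc_total = state.fpc.sum(axis=0)
            bare = fpc_total <= 0.0
            safe_total = np.maximum(fpc_total, 1e-300)
            ieff_avg = np.where(bare, 0.0, (state.fpc * ieff_pft).sum(axis=0) / safe_total)
            h_avg = np.where(
                bare, 0.0,
                (state.fpc * h_pft.reshape((-1, 1, 1))).sum(axis=0) / safe_total,
            )
            burn_memory *= scar_decay
            ieff_bf = np.maximum(0.0, 1.0 - burn_memory)
            ieff = fdi * ieff_avg * ieff_bf   # Eq. 6 triple product

            ignitions = light_y[d] * fcfg.ground_strike_fraction * area * ieff
            ros = fb.spread_rate_from_bed(bed, wind_y[d], me_scaling, fcfg)
            damp = np.maximum(
                0.0, 1.0 - fuel.class_moisture() / me_class_eff.reshape((-1, 1, 1))
            )
            consumed = (fuel.loads * cons_frac * damp).sum(axis=0)
            intensity = fb.fireline_intensity(h_avg, consumed, ros)
            spreading = (ros > 0.0) & (intensity >= fcfg.intensity_survival) & (ignitions > 0.0)
            d_area = np.where(
                spreading,
                fb.burned_area(ignitions, ros, wind_y[d], area, cum_burned, fcfg),
                0.0,
            )
            cum_burned += d_area
            burn_memory += d_area

            kill = fb.fire_mortality(intensity, susceptibility, fcfg)
            removed = state.fpc * kill * d_area[None]
            state = GridCellState(fpc=state.fpc - removed)
            killed_tree = removed[~is_grass].sum(axis=0)
            fuel.loads += vcfg.tree_kill_biomass * killed_tree[None] * kill_split
            fuel.loads[0] += vcfg.grass_live_load * removed[is_grass].sum(axis=0)
            # consume fuel over today's burned fraction
            fuel.loads -= fuel.loads * cons_frac * damp * d_area[None]
            fuel.loads[4] = vcfg.grass_live_load * state.grass_cover(model.pfts)

            if recording:
                acc["fires"] += ignitions
                acc["burned"] += d_area
                acc["ros"] += np.where(spreading, ros, 0.0)

        state = veg.establishment_and_growth(state, climate, model)
        _annual_fuel_turnover(state, fuel, model)
        tree = state.tree_cover(model.pfts)
        annual_cover[year] = float((tree * weights).sum())
        if recording:
            acc["cover"] += tree

    if years >= 2 * record_years:
        prev = annual_cover[years - 2 * record_years: years - record_years].mean()
        last = annual_cover[record_start:].mean()
        drift = abs(last - prev)
        if drift > model.experiment.drift_tolerance:
            log.append(
                f"WARNING: non-equilibrated spin-up: global tree-cover drift "
                f"{drift:.4f} over the final decades exceeds tolerance "
                f"{model.experiment.drift_tolerance}"
            )

    n_days = record_years * DAYS
    return RunResult(
        ox=ox,
        tree_cover=acc["cover"] / record_years,
        fires_per_yr=acc["fires"] / record_years,
        burned_frac_per_yr=acc["burned"] / record_years,
        mean_ros=acc["ros"] / n_days,
        mean_moisture=acc["moisture"] / n_days,
        annual_tree_cover=annual_cover,
        cell_area_km2=area,
        lat=lat,
        lon=lon,
        log=log,
    )
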