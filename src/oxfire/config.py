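"""Model configuration: PFT constants and the fire / vegetation / world /
experiment parameter blocks.

Everything a practitioner might need to change lives here as a dataclass
field with a default, and every field can be overridden from a TOML file with
sections [world], [pfts], [fire], [vegetation], [experiment] (see
configs/default.toml for a fully commented copy of the defaults).

The per-PFT base ignition efficiencies and the heat-of-combustion
coefficients alpha/beta are placeholders in the following sense: the
published per-PFT table behind them is not reproduced here, so beta is set to
a complete-combustion (bomb-calorimeter-like) value per growth form and
alpha = (h_PAL - beta) * 20.95 so that the heat of combustion at present-day
oxygen equals a conventional natural-fire value per growth form.  alpha is
therefore negative and heat released rises toward beta with increasing O2.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .oxygen import OX_PAL

TREE = "tree"
GRASS = "grass"

# Fuel size classes, fine to coarse dead fuel plus live grass.
FUEL_CLASSES = ("1h", "10h", "100h", "1000h", "live_grass")
N_FUEL = len(FUEL_CLASSES)
# Classes whose moisture tracks the fast fine-fuel pool (omega_nl): 1-h dead
# fuel and live grass.  The remainder track the slow woody pool (omega_o).
FINE_MOISTURE_CLASS = (True, False, False, False, True)


def _alpha(h_pal: float, beta: float) -> float:
    return (h_pal - beta) * OX_PAL


@dataclass(frozen=True)
class PFT:
    """Constants for one plant functional type."""

    name: str
    form: str                 # "tree" or "grass"
    group: str                # tropical / temperate / boreal / grass
    tc_min: float             # min coldest-month mean temperature, degC
    tc_max: float             # max coldest-month mean temperature, degC
    gdd_min: float            # min growing degree days, base 5 degC
    ieff_base: float          # prescribed ignition efficiency in [0, 1]
    alpha: float              # heat-of-combustion coefficient, kJ/kg * %O2
    beta: float               # asymptotic heat of combustion, kJ/kg
    susceptibility: float     # fire-mortality susceptibility in [0, 1]
    regrowth: float           # intrinsic logistic rate, 1/yr

    @property
    def is_grass(self) -> bool:
        return self.form == GRASS


# Growth-form heat-of-combustion scheme (kJ/kg): beta = complete combustion,
# h at PAL = conventional natural-fire value.
_BETA_TREE, _HPAL_TREE = 20000.0, 17500.0
_BETA_GRASS, _HPAL_GRASS = 18500.0, 16500.0


def default_pfts() -> tuple[PFT, ...]:
    """The nine PFTs: 2 tropical, 3 temperate and 2 boreal trees, 2 grasses.

    Bioclimatic limits are standard LPJ-family constants; ignition
    efficiencies and susceptibilities are conventional per-form values
    (grasses ignite easily and are top-killed but recover within a season;
    trees ignite less readily and lose cover for years).
    """
    at, bt = _alpha(_HPAL_TREE, _BETA_TREE), _BETA_TREE
    ag, bg = _alpha(_HPAL_GRASS, _BETA_GRASS), _BETA_GRASS
    return (
        PFT("tropical_broadleaf_evergreen", TREE, "tropical", 15.5, 1000.0, 0.0, 0.02, at, bt, 0.70, 0.08),
        PFT("tropical_broadleaf_raingreen", TREE, "tropical", 15.5, 1000.0, 0.0, 0.03, at, bt, 0.60, 0.10),
        PFT("temperate_needle_evergreen", TREE, "temperate", -2.0, 22.0, 900.0, 0.04, at, bt, 0.50, 0.08),
        PFT("temperate_broadleaf_evergreen", TREE, "temperate", 3.0, 18.8, 1200.0, 0.03, at, bt, 0.50, 0.08),
        PFT("temperate_broadleaf_summergreen", TREE, "temperate", -17.0, 15.5, 1200.0, 0.04, at, bt, 0.45, 0.09),
        PFT("boreal_needle_evergreen", TREE, "boreal", -32.5, -2.0, 600.0, 0.05, at, bt, 0.60, 0.06),
        PFT("boreal_summergreen", TREE, "boreal", -1000.0, -2.0, 350.0, 0.05, at, bt, 0.55, 0.07),
        PFT("c3_grass", GRASS, "grass", -1000.0, 1000.0, 0.0, 0.20, ag, bg, 1.00, 2.00),
        PFT("c4_grass", GRASS, "grass", 15.5, 1000.0, 0.0, 0.20, ag, bg, 1.00, 2.00),
    )


@dataclass(frozen=True)
class FireConfig:
    """Fire-engine constants.  All heats kJ/kg, moistures % dry mass."""

    oxygen_effects: bool = True        # False: force O2 = PAL everywhere
    pi_floor: float = 1.0              # PI floor (%) for scaling normalisation
    ground_strike_fraction: float = 0.2   # cloud-to-ground fraction of strikes
    fire_duration_min: float = 240.0   # representative single-day burn, minutes
    base_ros: float = 8.0              # dry, calm reference spread rate, m/min
    wind_coeff: float = 0.5            # ros wind multiplier per m/s
    bulk_density_ref: float = 20.0     # kg/m3; ros halves near this density
    intensity_survival: float = 50.0   # kW/m; weaker fires self-extinguish
    mortality_intensity_ref: float = 600.0    # kW/m saturation scale for kill
    nesterov_rain_reset: float = 3.0   # mm/day resetting the dryness index
    nesterov_scale: float = 5000.0     # degC^2 day scale mapping NI -> FDI
    dewpoint_depression: float = 30.0  # degC at rh=0 in the dewpoint proxy
    tau_fine: float = 2.0              # days, omega_nl relaxation
    tau_woody: float = 15.0            # days, omega_o relaxation
    moisture_floor: float = 5.0        # % dry mass at rh = 0
    moisture_scale: float = 220.0      # % dry mass; m_eq = floor + scale*rh^2
    # native (PAL) moisture of extinction per fuel class, % dry mass
    me_native: tuple[float, ...] = (30.0, 32.0, 34.0, 40.0, 20.0)
    # fraction of each class consumed when fire passes (before moisture damping)
    consumption: tuple[float, ...] = (1.0, 0.8, 0.4, 0.1, 1.0)
    # fuel-class particle bulk densities, kg/m3 (live grass is airy)
    class_density: tuple[float, ...] = (22.0, 25.0, 28.0, 30.0, 2.0)
    # classes contributing to the spread-relevant fuel bed (1000-h logs do not)
    spread_classes: tuple[bool, ...] = (True, True, True, False, True)
    length_breadth_wind: float = 0.06  # ellipse shape: LB = 1 + 8(1-e^-c*wind)
    # e-folding (days) of the burn-scar memory attenuating ignitions
    # (ieff_bf); scars stop blocking ignitions as fuels regrow.  The hard
    # cap on burned area per calendar year is separate and absolute.
    burn_scar_efolding_days: float = 150.0


@dataclass(frozen=True)
class VegetationConfig:
    """Minimal PFT population layer: carrying capacities, growth, litter."""

    fpc_max: float = 0.95           # maximum total cover
    fpc_seed: float = 0.002         # establishment cover for eligible PFTs
    decay_rate: float = 0.25        # 1/yr, decline of climate-excluded PFTs
    tree_precip_base: float = 250.0  # mm/yr; trees need more than this
    tree_precip_span: float = 300.0  # mm/yr from zero to full tree capacity
    grass_precip_base: float = 60.0
    grass_precip_span: float = 400.0
    grass_regrowth: float = 2.0     # 1/yr (grasses recover within a season)
    climate_smoothing: float = 0.1  # exponential smoothing of annual climate
    tree_litter: float = 0.35       # kg/m2/yr per unit tree FPC
    grass_litter: float = 0.25      # kg/m2/yr per unit grass FPC
    grass_live_load: float = 0.50   # standing live grass, kg/m2 per unit FPC
    tree_litter_split: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1, 0.0)
    fuel_decay: tuple[float, ...] = (0.35, 0.20, 0.10, 0.05, 0.0)  # 1/yr
    tree_kill_biomass: float = 2.0  # kg/m2 dead fuel per unit tree FPC killed
    kill_split: tuple[float, ...] = (0.2, 0.3, 0.3, 0.2, 0.0)
    forest_threshold: float = 0.60  # tree cover defining "forest"


@dataclass(frozen=True)
class BandClimate:
    """Climate archetype for one absolute-latitude band."""

    name: str
    lat_lo: float                 # band spans lat_lo <= |lat| < lat_hi
    lat_hi: float
    t_mean: float                 # annual mean temperature, degC
    t_amp: float                  # seasonal amplitude, degC
    p_annual: float               # mm/yr
    wet_prob: float               # annual-mean wet-day probability
    wet_persistence: float        # lag-1 correlation of the occurrence chain
    season_conc: float            # wet-day seasonality (+: wet warm season)
    gamma_shape: float            # wet-day amount distribution shape
    rh_base: float                # humidity proxy baseline in [0, 1]
    rh_season_amp: float          # humidity drop in the warm season
    rh_wet_boost: float           # humidity boost on wet days
    wind_mean: float              # m/s
    wind_sd: float
    lightning_per_km2_yr: float   # annual flash climatology
    lightning_wet_factor: float = 2.0   # convective boost on wet days
    lightning_season_amp: float = 1.5   # warm-season concentration of flashes
    # A band may mix two climates along longitude (rainforest vs savanna in
    # the real tropics): the trailing fraction of longitude columns uses the
    # variant archetype instead of the base one.
    variant: "BandClimate | None" = None
    variant_lon_fraction: float = 0.0


def savanna_variant() -> BandClimate:
    """Seasonally dry, lightning-rich savanna: wet warm season, desiccated
    dry season; already fire-rich at present-day oxygen."""
    return BandClimate("tropical_savanna", 0.0, 16.0, 25.0, 3.0, 900.0,
                       0.35, 0.30, 0.85, 0.7, 0.38, -0.20, 0.15, 3.5, 1.5, 70.0,
                       lightning_season_amp=0.1)


def maritime_variant() -> BandClimate:
    """Oceanic temperate climate: mild, humid year-round; fuels stay too wet
    to carry fire at any oxygen level in the experimental range."""
    return BandClimate("midlatitude_maritime", 30.0, 56.0, 11.0, 8.0, 1300.0,
                       0.55, 0.30, -0.20, 0.7, 0.80, 0.05, 0.12, 5.0, 1.5, 3.0)


def default_bands() -> tuple[BandClimate, ...]:
    """Latitudinal archetypes: perennially wet tropics with a savanna sector,
    arid subtropics, seasonally dry (winter-wet) mid latitudes, cold humid
    high latitudes."""
    return (
        BandClimate("tropics", 0.0, 16.0, 26.0, 2.0, 2200.0,
                    0.65, 0.30, 0.10, 0.7, 0.80, 0.04, 0.10, 2.5, 1.2, 25.0,
                    lightning_wet_factor=1.5,
                    variant=savanna_variant(), variant_lon_fraction=1 / 3),
        BandClimate("subtropics_arid", 16.0, 30.0, 22.0, 8.0, 280.0,
                    0.10, 0.30, -0.20, 0.7, 0.18, 0.08, 0.25, 4.0, 1.5, 4.0),
        BandClimate("midlatitude", 30.0, 56.0, 11.0, 13.0, 760.0,
                    0.30, 0.40, -0.90, 0.7, 0.30, 0.25, 0.15, 3.5, 1.5, 6.0,
                    variant=maritime_variant(), variant_lon_fraction=1 / 3),
        BandClimate("high_latitude", 56.0, 90.1, -2.0, 16.0, 550.0,
                    0.50, 0.30, 0.20, 0.7, 0.82, 0.04, 0.10, 3.0, 1.2, 1.0),
    )


@dataclass(frozen=True)
class WorldConfig:
    """Synthetic-world grid and climate-band parameters."""

    n_lat: int = 36
    n_lon: int = 18
    bands: tuple[BandClimate, ...] = field(default_factory=default_bands)

    def __post_init__(self):
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid shape must be positive")


@dataclass(frozen=True)
class ExperimentConfig:
    """Sweep layout: O2 levels, spin-up and averaging windows."""

    o2_levels: tuple[float, ...] = (OX_PAL,) + tuple(float(v) for v in range(21, 36))
    spinup_years: int = 200          # scaled-down from the full 1500-yr spin-up
    record_years: int = 10           # final decade averaged as output
    no_fire_baseline: bool = True
    drift_tolerance: float = 0.02    # global tree-cover drift flagged beyond this
    moisture_band_edges: tuple[float, ...] = (20.0, 40.0, 60.0)   # % dry mass

    def __post_init__(self):
        for ox in self.o2_levels:
            if ox < OX_PAL or ox > 35.0:
                raise ValueError("swept O2 levels must lie in [20.95, 35]")


@dataclass(frozen=True)
class ModelConfig:
    """Bundle of everything except the world grid."""

    pfts: tuple[PFT, ...] = field(default_factory=default_pfts)
    fire: FireConfig = field(default_factory=FireConfig)
    vegetation: VegetationConfig = field(default_factory=VegetationConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    def __post_init__(self):
        forms = [p.form for p in self.pfts]
        if len(self.pfts) != 9 or forms.count(GRASS) != 2:
            raise ValueError("expected 9 PFTs: 7 trees and 2 grasses")


def _override(dc, table: dict):
    """Rebuild a frozen dataclass with fields overridden from a TOML table."""
    names = {f.name for f in dataclasses.fields(dc)}
    unknown = set(table) - names
    if unknown:
        raise KeyError(f"unknown config keys {sorted(unknown)} for {type(dc).__name__}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in table.items()
    }
    return dataclasses.replace(dc, **coerced)


def load_config(path: str | Path) -> tuple[WorldConfig, ModelConfig]:
    """Load a TOML config, overriding defaults section by section.

    [pfts] holds one sub-table per PFT name with the fields to override;
    [world.bands] likewise one sub-table per band name.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    world = WorldConfig()
    wtab = dict(raw.get("world", {}))
    band_overrides = wtab.pop("bands", {})
    if band_overrides:
        bands = tuple(
            _override(b, band_overrides.get(b.name, {})) for b in world.bands
        )
        world = dataclasses.replace(world, bands=bands)
    world = _override(world, wtab)

    pfts = tuple(
        _override(p, raw.get("pfts", {}).get(p.name, {})) for p in default_pfts()
    )
    model = ModelConfig(
        pfts=pfts,
        fire=_override(FireConfig(), raw.get("fire", {})),
        vegetation=_override(VegetationConfig(), raw.get("vegetation", {})),
        experiment=_override(ExperimentConfig(), raw.get("experiment", {})),
    )
    return world, model
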