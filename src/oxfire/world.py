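"""Synthetic gridded daily weather and lightning forcing.

Stands in for real half-degree climate forcing with the minimal latitudinal
structure the fire-oxygen experiment hinges on: perennially wet warm tropics,
arid subtropics, seasonally dry (winter-wet, summer-dry) mid latitudes, and
cold high latitudes whose low evaporative demand keeps fuels moist.

Precipitation occurrence follows a two-state (wet/dry) Markov chain with
seasonally modulated stationary wet probability and fixed persistence;
wet-day amounts are gamma distributed.  Temperature and the relative-humidity
proxy carry sinusoidal seasonal cycles plus white noise; lightning follows a
warm-season climatology with a convective boost on wet days.  Everything is
generated from one seeded numpy Generator, so a fixed seed reproduces the
forcing bit for bit — the oxygen sweep runs every O2 level against the
identical weather stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .config import BandClimate, WorldConfig

DAYS = 365
EARTH_RADIUS_KM = 6371.0
_WARM_PEAK_DOY = 196  # northern-hemisphere warm-season peak


@dataclass
class DailyForcing:
    """Daily weather + lightning for every cell; arrays (n_days, n_lat, n_lon)."""

    temp: np.ndarray       # degC
    precip: np.ndarray     # mm/day
    rh: np.ndarray         # relative-humidity proxy in [0, 1]
    wind: np.ndarray       # m/s
    lightning: np.ndarray  # strikes/km2/day (all flashes; ground fraction applied later)
    lat: np.ndarray        # (n_lat,) cell-centre latitudes, deg
    lon: np.ndarray        # (n_lon,)

    def __post_init__(self):
        for name in ("temp", "precip", "rh", "wind", "lightning"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.precip < 0) or np.any(self.lightning < 0):
            raise ValueError("precipitation and lightning must be >= 0")

    @property
    def n_days(self) -> int:
        return self.temp.shape[0]

    def to_dataset(self) -> xr.Dataset:
        coords = {"time": np.arange(self.n_days), "lat": self.lat, "lon": self.lon}
        return xr.Dataset(
            {
                name: (("time", "lat", "lon"), getattr(self, name))
                for name in ("temp", "precip", "rh", "wind", "lightning")
            },
            coords=coords,
        )


def lat_centers(cfg: WorldConfig) -> np.ndarray:
    edges = np.linspace(-90.0, 90.0, cfg.n_lat + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def lon_centers(cfg: WorldConfig) -> np.ndarray:
    edges = np.linspace(-180.0, 180.0, cfg.n_lon + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def cell_areas_km2(cfg: WorldConfig) -> np.ndarray:
    """Cell areas (n_lat, n_lon): spherical zone area split across longitudes."""
    edges = np.radians(np.linspace(-90.0, 90.0, cfg.n_lat + 1))
    zone = 2.0 * np.pi * EARTH_RADIUS_KM**2 * (np.sin(edges[1:]) - np.sin(edges[:-1]))
    return np.repeat((zone / cfg.n_lon)[:, None], cfg.n_lon, axis=1)


def band_for_lat(cfg: WorldConfig, lat: float) -> BandClimate:
    a = abs(lat)
    for band in cfg.bands:
        if band.lat_lo <= a < band.lat_hi:
            return band
    raise ValueError(f"no climate band covers latitude {lat}")


def cell_bands(cfg: WorldConfig) -> list[list[BandClimate]]:
    """Climate archetype per cell: the base band of the row, with the
    trailing longitude columns switched to the band's variant (if any)."""
    out = []
    for la in lat_centers(cfg):
        base = band_for_lat(cfg, la)
        k = round(base.variant_lon_fraction * cfg.n_lon) if base.variant else 0
        row = [base] * (cfg.n_lon - k) + [base.variant] * k
        out.append(row)
    return out


def _band_field(cfg: WorldConfig, attr: str) -> np.ndarray:
    """Per-cell value of a band parameter, shaped (n_lat, n_lon)."""
    return np.asarray(
        [[getattr(b, attr) for b in row] for row in cell_bands(cfg)], dtype=float
    )


def _season_phase(cfg: WorldConfig, doy: np.ndarray) -> np.ndarray:
    """(n_days, n_lat, 1): +1 at local warm-season peak, -1 in deep winter."""
    north = np.cos(2.0 * np.pi * (doy - _WARM_PEAK_DOY) / DAYS)
    hemi = np.where(lat_centers(cfg) >= 0.0, 1.0, -1.0)
    return north[:, None, None] * hemi[None, :, None]


class ForcingGenerator:
    """Streams one year of forcing at a time from a persistent seeded RNG.

    Carrying the generator and the Markov wet/dry state across years keeps
    memory flat for long spin-ups while remaining fully deterministic.
    """

    def __init__(self, cfg: WorldConfig, seed: int):
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self._lat = lat_centers(cfg)
        self._lon = lon_centers(cfg)
        shape = (cfg.n_lat, cfg.n_lon)
        # start from the annual-mean stationary wet probability
        pi0 = np.broadcast_to(_band_field(cfg, "wet_prob"), shape)
        self.wet = self.rng.random(shape) < pi0

    def year(self) -> DailyForcing:
        cfg = self.cfg
        nlat, nlon = cfg.n_lat, cfg.n_lon
        doy = np.arange(DAYS)
        phase = _season_phase(cfg, doy)                      # (365, nlat, 1)

        pi0 = _band_field(cfg, "wet_prob")[None]             # (1, nlat, 1)
        conc = _band_field(cfg, "season_conc")[None]
        pers = _band_field(cfg, "wet_persistence")[None]
        pi_d = np.clip(pi0 * (1.0 + conc * phase), 0.02, 0.98)
        p11 = pi_d + pers * (1.0 - pi_d)
        p01 = pi_d * (1.0 - pers)

        u = self.rng.random((DAYS, nlat, nlon))
        wet = np.empty((DAYS, nlat, nlon), dtype=bool)
        state = self.wet
        for d in range(DAYS):
            thresh = np.where(state, p11[d], p01[d])
            state = u[d] < thresh
            wet[d] = state
        self.wet = state

        # wet-day amounts: gamma with mean matching the annual total
        shape_k = _band_field(cfg, "gamma_shape")[None]
        mean_pi = pi_d.mean(axis=0, keepdims=True)           # (1, nlat, 1)
        mu_wet = _band_field(cfg, "p_annual")[None] / (DAYS * mean_pi)
        g = self.rng.gamma(np.broadcast_to(shape_k, (DAYS, nlat, nlon)), 1.0)
        precip = np.where(wet, g * (mu_wet / shape_k), 0.0)

        temp = (
            _band_field(cfg, "t_mean")[None]
            + _band_field(cfg, "t_amp")[None] * phase
            + self.rng.normal(0.0, 1.5, (DAYS, nlat, nlon))
        )
        rh = np.clip(
            _band_field(cfg, "rh_base")[None]
            - _band_field(cfg, "rh_season_amp")[None] * phase
            + _band_field(cfg, "rh_wet_boost")[None] * wet
            + self.rng.normal(0.0, 0.03, (DAYS, nlat, nlon)),
            0.02,
            0.98,
        )
        wind = np.maximum(
            0.1,
            _band_field(cfg, "wind_mean")[None]
            + self.rng.normal(0.0, 1.0, (DAYS, nlat, nlon))
            * _band_field(cfg, "wind_sd")[None],
        )

        # lightning: warm-season weighting plus convective wet-day boost,
        # normalised so the annual expectation matches the band climatology
        wf = _band_field(cfg, "lightning_wet_factor")[None]
        w_season = np.maximum(0.05, 1.0 + _band_field(cfg, "lightning_season_amp")[None] * phase)
        norm = (w_season * (1.0 + wf * pi_d)).mean(axis=0, keepdims=True)
        base = _band_field(cfg, "lightning_per_km2_yr")[None] / DAYS
        lightning = base * w_season * (1.0 + wf * wet) / norm

        return DailyForcing(temp, precip, rh, wind, lightning, self._lat, self._lon)


def generate_forcing(cfg: WorldConfig, years: int, seed: int) -> DailyForcing:
    """All years of daily forcing in one container (use the generator
    directly for long spin-ups)."""
    if years < 1:
        raise ValueError("years must be >= 1")
    gen = ForcingGenerator(cfg, seed)
    parts = [gen.year() for _ in range(years)]
    return DailyForcing(
        *[np.concatenate([getattr(p, n) for p in parts]) for n in
          ("temp", "precip", "rh", "wind", "lightning")],
        parts[0].lat,
        parts[0].lon,
    )


def mini_world_config() -> WorldConfig:
    """6 x 3 grid whose latitude rows sample the tropical, mid-latitude and
    high-latitude archetypes in both hemispheres (cell centres at +-15, +-45,
    +-75 deg)."""
    return WorldConfig(n_lat=6, n_lon=3)


def make_fixture(name: str) -> tuple[WorldConfig, DailyForcing]:
    """Tiny deterministic forcing sets for unit tests.

    ``single_cell_wet``: two years of daily rain (> 4 mm every day), warm and
    humid.  ``single_cell_dry``: sparse rain only within the first 90 days,
    then permanently dry.  ``mini_world``: five seeded years on the 6 x 3
    archetype grid.
    """
    if name == "mini_world":
        cfg = mini_world_config()
        return cfg, generate_forcing(cfg, years=5, seed=0)

    cfg = WorldConfig(n_lat=1, n_lon=1)
    n = 2 * DAYS
    d = np.arange(n)
    season = np.cos(2.0 * np.pi * (d - _WARM_PEAK_DOY) / DAYS)
    shape = (n, 1, 1)

    def grid(x):
        return np.broadcast_to(np.asarray(x, dtype=float).reshape(-1, 1, 1), shape).copy()

    if name == "single_cell_wet":
        forcing = DailyForcing(
            temp=grid(26.0 + 2.0 * season),
            precip=grid(6.0 + 1.9 * season),
            rh=grid(np.full(n, 0.85)),
            wind=grid(np.full(n, 2.5)),
            lightning=grid(np.full(n, 15.0 / DAYS)),
            lat=np.array([0.0]),
            lon=np.array([0.0]),
        )
    elif name == "single_cell_dry":
        # enough early-season rain to grow a grassy fuel bed, then bone dry
        precip = np.where((d < 90) & (d % 3 == 0), 12.0, 0.0)
        forcing = DailyForcing(
            temp=grid(25.0 + 5.0 * season),
            precip=grid(precip),
            rh=grid(0.22 + 0.2 * (precip > 0)),
            wind=grid(np.full(n, 4.0)),
            lightning=grid(np.full(n, 4.0 / DAYS)),
            lat=np.array([0.0]),
            lon=np.array([0.0]),
        )
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return cfg, forcing
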