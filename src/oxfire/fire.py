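"""SPITFIRE-style daily fire behaviour with all oxygen dependence routed
through :mod:`oxfire.oxygen`.

The engine is deliberately desk-scale: one representative fire day with a
fixed burn duration, no multi-day burning or fire coalescence.  Oxygen enters
through exactly three pathways — the ignition-efficiency scaling, the
moisture-of-extinction scaling that weakens the Rothermel-type moisture
damping, and the per-PFT heat of combustion entering Byram's fireline
intensity.  At 20.95 % vol. O2 every pathway reduces to the unscaled
baseline.

All functions are element-wise over numpy arrays; the daily grid loop in
:mod:`oxfire.simulation` calls them on whole-grid fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FINE_MOISTURE_CLASS, FireConfig, N_FUEL
from .oxygen import moisture_extinction_scaling


@dataclass
class FuelBed:
    """Per-cell fuel state: loads by size class plus the two moisture pools.

    ``loads`` has the class axis first: (n_class, ...) kg/m2 of 1-h, 10-h,
    100-h, 1000-h dead fuel and live grass.  ``moisture_fine`` is the fast
    pool (omega_nl: 1-h dead fuel and live grass), ``moisture_woody`` the
    slow pool (omega_o), both % dry mass.
    """

    loads: np.ndarray
    moisture_fine: np.ndarray
    moisture_woody: np.ndarray

    def __post_init__(self):
        if self.loads.shape[0] != N_FUEL:
            raise ValueError(f"expected {N_FUEL} fuel classes")
        if np.any(self.loads < 0):
            raise ValueError("fuel loads must be >= 0")
        if np.any(self.moisture_fine <= 0) or np.any(self.moisture_woody <= 0):
            raise ValueError("fuel moistures must be > 0 % dry mass")

    def class_moisture(self) -> np.ndarray:
        """Moisture per class, (n_class, ...): fine pool for 1-h and live
        grass, woody pool for the rest."""
        fine = np.asarray(FINE_MOISTURE_CLASS)
        return np.where(
            fine.reshape((-1,) + (1,) * (self.loads.ndim - 1)),
            self.moisture_fine[None],
            self.moisture_woody[None],
        )


@dataclass
class FireDay:
    """One day of fire diagnostics for every cell."""

    n_ignitions: np.ndarray    # expected fires ignited, 1/cell/day
    ros: np.ndarray            # forward rate of spread, m/min
    intensity: np.ndarray      # fireline intensity, kW/m
    area_burned: np.ndarray    # fraction of cell burned today, in [0, 1]


# ---------------------------------------------------------------------------
# fire danger


def nesterov_step(index, temp, precip, rh, cfg: FireConfig):
    """One daily update of the cumulative dryness (Nesterov-type) index.

    The index accumulates max(T, 0) * (T - Td) using a humidity-proxy
    dewpoint Td = T - depression * (1 - rh), and resets to zero on days with
    precipitation above the reset threshold.
    """
    temp = np.asarray(temp, dtype=float)
    increment = np.maximum(temp, 0.0) * cfg.dewpoint_depression * (1.0 - np.asarray(rh))
    out = np.where(np.asarray(precip) > cfg.nesterov_rain_reset, 0.0,
                   np.asarray(index) + increment)
    return out


def fdi_from_index(index, cfg: FireConfig):
    """Map the dryness index to a fire danger index in [0, 1) with a
    saturating exponential."""
    return 1.0 - np.exp(-np.asarray(index, dtype=float) / cfg.nesterov_scale)


def fire_danger_index(temps, precips, rhs, cfg: FireConfig | None = None):
    """FDI after running the dryness index over a forcing history.

    Convenience wrapper over :func:`nesterov_step`; the simulation keeps the
    running index as state instead of replaying history.
    """
    cfg = cfg or FireConfig()
    index = np.zeros_like(np.asarray(temps, dtype=float)[0])
    for t, p, r in zip(temps, precips, rhs):
        index = nesterov_step(index, t, p, r, cfg)
    return fdi_from_index(index, cfg)


# ---------------------------------------------------------------------------
# ignitions and spread


def expected_ignitions(lightning, ieff, cell_area_km2, cfg: FireConfig):
    """Expected fire starts per cell per day.

    ``lightning`` is the all-flash density (strikes/km2/day); only the
    cloud-to-ground fraction can ignite, and each ground strike succeeds with
    overall ignition efficiency ``ieff``.
    """
    lightning = np.asarray(lightning, dtype=float)
    if np.any(lightning < 0):
        raise ValueError("lightning density must be >= 0")
    return lightning * cfg.ground_strike_fraction * np.asarray(cell_area_km2) * np.asarray(ieff)


def effective_extinction(ox: float, me_native, cfg: FireConfig):
    """Per-class effective moisture of extinction at oxygen level ``ox``."""
    return np.asarray(me_native, dtype=float) * moisture_extinction_scaling(ox)


def _spread_weights(fuel: FuelBed, cfg: FireConfig) -> np.ndarray:
    mask = np.asarray(cfg.spread_classes, dtype=float)
    return fuel.loads * mask.reshape((-1,) + (1,) * (fuel.loads.ndim - 1))


def spread_moisture(fuel: FuelBed, cfg: FireConfig):
    """Load-weighted moisture of the spread-relevant fuel bed, % dry mass.

    Cells with no spread-relevant fuel report an effectively infinite
    moisture so they can never carry fire.
    """
    w = _spread_weights(fuel, cfg)
    total = w.sum(axis=0)
    m = np.where(total > 0.0, (w * fuel.class_moisture()).sum(axis=0) / np.maximum(total, 1e-300), np.inf)
    return m


def bed_bulk_density(fuel: FuelBed, cfg: FireConfig):
    """Load-weighted particle bulk density of the spread-relevant bed."""
    w = _spread_weights(fuel, cfg)
    total = w.sum(axis=0)
    dens = np.asarray(cfg.class_density, dtype=float).reshape(
        (-1,) + (1,) * (fuel.loads.ndim - 1)
    )
    return np.where(total > 0.0, (w * dens).sum(axis=0) / np.maximum(total, 1e-300),
                    cfg.bulk_density_ref)


def moisture_damping(moisture, me_effective):
    """Rothermel moisture damping eta_M(r), r = moisture / effective Me.

    Cubic damping: 1 - 2.59 r + 5.11 r^2 - 3.52 r^3, exactly 0 at r = 1 and
    monotone decreasing on [0, 1]; clamped to 0 beyond extinction (an
    infinite moisture, signalling an empty bed, damps to 0).
    """
    r_raw = np.asarray(moisture, dtype=float) / np.asarray(me_effective, dtype=float)
    r = np.minimum(r_raw, 1.0)
    eta = 1.0 - 2.59 * r + 5.11 * r**2 - 3.52 * r**3
    return np.where(r_raw >= 1.0, 0.0, np.maximum(eta, 0.0))


@dataclass
class BedProperties:
    """Spread-relevant aggregates of a fuel bed, computed once per day."""

    total_load: np.ndarray     # kg/m2 in the spread classes
    moisture: np.ndarray       # load-weighted moisture, % (inf if empty)
    me_native: np.ndarray      # load-weighted native extinction moisture, %
    bulk_density: np.ndarray   # load-weighted particle density, kg/m3


def bed_properties(fuel: FuelBed, cfg: FireConfig) -> BedProperties:
    w = _spread_weights(fuel, cfg)
    total = w.sum(axis=0)
    safe = np.maximum(total, 1e-300)
    shape = (-1,) + (1,) * (fuel.loads.ndim - 1)
    me = np.asarray(cfg.me_native, dtype=float).reshape(shape)
    dens = np.asarray(cfg.class_density, dtype=float).reshape(shape)
    return BedProperties(
        total_load=total,
        moisture=np.where(total > 0.0, (w * fuel.class_moisture()).sum(axis=0) / safe, np.inf),
        me_native=np.where(total > 0.0, (w * me).sum(axis=0) / safe, np.mean(cfg.me_native)),
        bulk_density=np.where(total > 0.0, (w * dens).sum(axis=0) / safe, cfg.bulk_density_ref),
    )


def spread_rate_from_bed(bed: BedProperties, wind, me_scaling: float, cfg: FireConfig):
    """Rothermel-style spread rate from precomputed bed aggregates."""
    eta = moisture_damping(bed.moisture, bed.me_native * me_scaling)
    wind_factor = 1.0 + cfg.wind_coeff * np.asarray(wind, dtype=float)
    packing = 1.0 + bed.bulk_density / cfg.bulk_density_ref
    return cfg.base_ros * eta * wind_factor / packing


def rate_of_spread(fuel: FuelBed, wind, ox: float, cfg: FireConfig):
    """Forward rate of spread, m/min.

    Zero when the load-weighted bed moisture reaches the effective moisture
    of extinction (native constants scaled by the oxygen factor); otherwise a
    Rothermel-style product of a reference dry-fuel rate, the cubic moisture
    damping, a linear wind factor, and a packing (bulk density) attenuation.
    Non-decreasing in oxygen and wind, non-increasing in bulk density.
    """
    if np.any(np.asarray(wind) < 0):
        raise ValueError("wind must be >= 0")
    return spread_rate_from_bed(
        bed_properties(fuel, cfg), wind, moisture_extinction_scaling(ox), cfg
    )


def fuel_consumed(fuel: FuelBed, ox: float, cfg: FireConfig, me_class=None):
    """Fuel consumed where fire passes, kg/m2 (per unit burned area).

    Per-class consumption fraction damped linearly by the class moisture
    relative to its effective extinction moisture; classes wetter than
    extinction do not burn.  ``me_class`` may carry precomputed effective
    extinction moistures.
    """
    if me_class is None:
        me_class = effective_extinction(ox, cfg.me_native, cfg)
    shape = (-1,) + (1,) * (fuel.loads.ndim - 1)
    me_class = np.asarray(me_class, dtype=float).reshape(shape)
    frac = np.asarray(cfg.consumption, dtype=float).reshape(shape)
    damp = np.maximum(0.0, 1.0 - fuel.class_moisture() / me_class)
    return (fuel.loads * frac * damp).sum(axis=0)


def fireline_intensity(h_avg, consumed, ros):
    """Byram's fireline intensity I = h * w * (ros/60), kW/m.

    ``h_avg`` kJ/kg (FPC-weighted cell mean heat of combustion), ``consumed``
    kg/m2, ``ros`` m/min converted to m/s.
    """
    h = np.asarray(h_avg, dtype=float)
    w = np.asarray(consumed, dtype=float)
    r = np.asarray(ros, dtype=float)
    if np.any(h < 0) or np.any(w < 0) or np.any(r < 0):
        raise ValueError("intensity inputs must be >= 0")
    return h * w * (r / 60.0)


def length_to_breadth(wind, cfg: FireConfig):
    """Fire-ellipse length-to-breadth ratio, 1 (calm) to 9 (strong wind)."""
    return 1.0 + 8.0 * (1.0 - np.exp(-cfg.length_breadth_wind * np.asarray(wind, dtype=float)))


def burned_area(n_ignitions, ros, wind, cell_area_km2, cum_burned, cfg: FireConfig):
    """Fraction of the cell burned today.

    Each fire burns an ellipse with forward axis ros * duration and
    length-to-breadth set by wind; the day's total is capped at the cell's
    remaining unburned fraction for the calendar year.
    """
    n = np.asarray(n_ignitions, dtype=float)
    r = np.asarray(ros, dtype=float)
    if np.any(n < 0) or np.any(r < 0):
        raise ValueError("ignitions and ros must be >= 0")
    length_m = r * cfg.fire_duration_min
    lb = length_to_breadth(wind, cfg)
    per_fire_km2 = (np.pi / 4.0) * length_m**2 / lb / 1e6
    frac = n * per_fire_km2 / np.asarray(cell_area_km2, dtype=float)
    return np.minimum(frac, np.maximum(0.0, 1.0 - np.asarray(cum_burned, dtype=float)))


def fire_mortality(intensity, susceptibility, cfg: FireConfig):
    """Kill fraction within the burned area: susceptibility-scaled saturating
    function of fireline intensity, asymptote = susceptibility <= 1."""
    i = np.asarray(intensity, dtype=float)
    if np.any(i < 0):
        raise ValueError("intensity must be >= 0")
    return np.asarray(susceptibility, dtype=float) * (
        1.0 - np.exp(-i / cfg.mortality_intensity_ref)
    )


def equilibrium_moisture(rh, cfg: FireConfig):
    """Equilibrium fuel moisture (% dry mass) from the humidity proxy."""
    return cfg.moisture_floor + cfg.moisture_scale * np.asarray(rh, dtype=float) ** 2


def relax_moisture(moisture, target, tau: float):
    """Exponential relaxation of a moisture pool toward its equilibrium with
    time constant ``tau`` days (exact one-day integration)."""
    f = 1.0 - np.exp(-1.0 / tau)
    return np.asarray(moisture) + f * (np.asarray(target) - np.asarray(moisture))
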