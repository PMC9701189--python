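"""Minimal PFT population layer.

Supplies foliar projective cover (FPC) to the fire engine and absorbs fire
mortality.  Biogeography is a transparent surrogate for a full DGVM: annual
logistic growth toward climate-set carrying capacities, with bioclimatic
limits (coldest-month temperature window, growing-degree-day minimum)
deciding which PFTs can occur, precipitation setting how much cover trees
and grasses can reach, and trees outcompeting grasses for shared space at
equilibrium.  The annual step uses the exact one-year integration of the
continuous logistic, so a constant-climate cell follows the closed-form
logistic trajectory exactly — which the tests exploit.

With fire disabled the layer converges to its climate-limited potential,
the denominator of the fire-suppression metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, PFT, VegetationConfig

GDD_BASE = 5.0


@dataclass
class ClimateSummary:
    """Smoothed annual climate statistics driving establishment and growth."""

    gdd: np.ndarray            # growing degree days, base 5 degC
    coldest_month: np.ndarray  # mean temperature of the coldest month, degC
    precip: np.ndarray         # annual precipitation, mm/yr

    def blend(self, other: "ClimateSummary", alpha: float) -> "ClimateSummary":
        return ClimateSummary(
            gdd=(1 - alpha) * self.gdd + alpha * other.gdd,
            coldest_month=(1 - alpha) * self.coldest_month + alpha * other.coldest_month,
            precip=(1 - alpha) * self.precip + alpha * other.precip,
        )


@dataclass
class GridCellState:
    """Dynamic vegetation state for every cell: FPC per PFT, (n_pft, ...)."""

    fpc: np.ndarray

    def __post_init__(self):
        if np.any(self.fpc < 0) or np.any(self.fpc.sum(axis=0) > 1.0 + 1e-12):
            raise ValueError("FPC must be >= 0 with total <= 1")

    def tree_cover(self, pfts: tuple[PFT, ...]) -> np.ndarray:
        trees = np.array([not p.is_grass for p in pfts])
        return self.fpc[trees].sum(axis=0)

    def grass_cover(self, pfts: tuple[PFT, ...]) -> np.ndarray:
        grasses = np.array([p.is_grass for p in pfts])
        return self.fpc[grasses].sum(axis=0)


def annual_climate(temp: np.ndarray, precip: np.ndarray) -> ClimateSummary:
    """Summaries from one year (365, ...) of daily forcing."""
    months = np.array_split(temp, 12, axis=0)
    coldest = np.min([m.mean(axis=0) for m in months], axis=0)
    gdd = np.maximum(temp - GDD_BASE, 0.0).sum(axis=0)
    return ClimateSummary(gdd=gdd, coldest_month=coldest, precip=precip.sum(axis=0))


def eligibility(pfts: tuple[PFT, ...], climate: ClimateSummary) -> np.ndarray:
    """(n_pft, ...) boolean: PFT within its bioclimatic limits."""
    tc = climate.coldest_month[None]
    gdd = climate.gdd[None]
    tc_min = np.array([p.tc_min for p in pfts]).reshape((-1,) + (1,) * tc.ndim)[:, 0]
    tc_max = np.array([p.tc_max for p in pfts]).reshape((-1,) + (1,) * tc.ndim)[:, 0]
    gdd_min = np.array([p.gdd_min for p in pfts]).reshape((-1,) + (1,) * tc.ndim)[:, 0]
    return (tc >= tc_min) & (tc <= tc_max) & (gdd >= gdd_min)


def tree_capacity(precip, cfg: VegetationConfig):
    """Maximum tree cover a cell's annual precipitation supports."""
    x = (np.asarray(precip, dtype=float) - cfg.tree_precip_base) / cfg.tree_precip_span
    return cfg.fpc_max * np.clip(x, 0.0, 1.0)


def grass_capacity(precip, cfg: VegetationConfig):
    x = (np.asarray(precip, dtype=float) - cfg.grass_precip_base) / cfg.grass_precip_span
    return cfg.fpc_max * np.clip(x, 0.0, 1.0)


def logistic_step(x, rate, capacity):
    """Exact one-year integration of dx/dt = r x (1 - x/K).

    Matches the closed form K / (1 + ((K - x0)/x0) e^(-r t)) sampled
    annually; returns 0 where the capacity is 0.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(capacity, dtype=float)
    er = np.exp(np.asarray(rate, dtype=float))
    denom = k + x * (er - 1.0)
    return np.where((k > 0.0) & (denom > 0.0), k * x * er / np.maximum(denom, 1e-300), 0.0)


def _grow_group(fpc_group, rates, eligible, capacity, cfg: VegetationConfig):
    """Shared-capacity logistic growth for one growth form.

    Climate-excluded members decay; eligible members (re)establish at the
    seed cover, then the group total follows the exact logistic toward the
    shared capacity and members keep their relative proportions.
    """
    fpc = np.where(eligible, fpc_group, fpc_group * (1.0 - cfg.decay_rate))
    fpc = np.where(eligible & (capacity[None] > 0.0),
                   np.maximum(fpc, cfg.fpc_seed), fpc)
    total = fpc.sum(axis=0)
    r_mean = np.where(total > 0.0,
                      (fpc * rates.reshape((-1,) + (1,) * (fpc.ndim - 1))).sum(axis=0)
                      / np.maximum(total, 1e-300), 0.0)
    new_total = logistic_step(total, r_mean, capacity)
    scale = np.where(total > 0.0, new_total / np.maximum(total, 1e-300), 0.0)
    return fpc * scale[None]


def establishment_and_growth(state: GridCellState, climate: ClimateSummary,
                             model: ModelConfig) -> GridCellState:
    """Annual vegetation update: trees first (they pre-empt space), grasses
    fill what precipitation allows of the remainder."""
    cfg = model.vegetation
    pfts = model.pfts
    elig = eligibility(pfts, climate)
    is_grass = np.array([p.is_grass for p in pfts])
    rates = np.array([p.regrowth for p in pfts])

    fpc = state.fpc.copy()
    k_tree = tree_capacity(climate.precip, cfg)
    fpc[~is_grass] = _grow_group(fpc[~is_grass], rates[~is_grass],
                                 elig[~is_grass], k_tree, cfg)
    tree_total = fpc[~is_grass].sum(axis=0)

    k_grass = np.minimum(grass_capacity(climate.precip, cfg),
                         np.maximum(cfg.fpc_max - tree_total, 0.0))
    fpc[is_grass] = _grow_group(fpc[is_grass], rates[is_grass],
                                elig[is_grass], k_grass, cfg)
    return GridCellState(fpc=fpc)


def apply_fire_mortality(state: GridCellState, kill_fraction: np.ndarray,
                         burned_fraction: np.ndarray) -> tuple[GridCellState, np.ndarray]:
    """Remove burned-and-killed cover: fpc <- fpc * (1 - kill * burned).

    Returns the updated state and the FPC removed per PFT (the simulation
    converts killed tree cover into dead fuel).
    """
    kill = np.asarray(kill_fraction, dtype=float)
    if np.any(kill < 0) or np.any(kill > 1):
        raise ValueError("kill fractions must lie in [0, 1]")
    removed = state.fpc * kill * np.asarray(burned_fraction, dtype=float)
    return GridCellState(fpc=state.fpc - removed), removed


def potential_cover(climate: ClimateSummary, model: ModelConfig) -> np.ndarray:
    """Analytic no-fire equilibrium tree cover (the logistic carrying
    capacity where any tree PFT is climatically eligible)."""
    elig = eligibility(model.pfts, climate)
    any_tree = np.any(
        [e for e, p in zip(elig, model.pfts) if not p.is_grass], axis=0
    )
    return np.where(any_tree, tree_capacity(climate.precip, model.vegetation), 0.0)
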