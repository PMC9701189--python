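"""Oxygen dependence of fire: ignition probability, moisture of extinction,
heat of combustion.

Combustion experiments on natural fuels show that the likelihood that a
lightning stroke ignites dead fine fuel rises steeply with the atmospheric
oxygen mixing ratio, that the fuel moisture content above which a fire cannot
spread (the moisture of extinction) rises roughly linearly with oxygen, and
that the heat released per unit fuel burned increases toward its
complete-combustion value as oxygen rises.  This module implements those
three empirical relationships as pure functions, each normalised around the
present atmospheric level (PAL, 20.95 % vol. O2) so that at PAL every scaling
factor is exactly 1 and a simulator using them reduces to its oxygen-free
baseline.

All functions accept scalars or numpy arrays and are used element-wise by the
fire engine.  Oxygen is a mixing ratio in % by volume, restricted to the
validity range of the underlying combustion experiments ([16, 35] % vol.);
fuel moisture is % of dry mass (values above 100 % are legitimate on a
dry-mass basis).
"""

from __future__ import annotations

import math

import numpy as np

#: Present atmospheric level of oxygen, % by volume.
OX_PAL = 20.95

#: Validity range of the combustion experiments behind the fits, % by volume.
#: Dry fuels fail to ignite below ~17 % O2, so the lower bound is academic.
OX_MIN = 16.0
OX_MAX = 35.0


class OxygenRangeError(ValueError):
    """Oxygen mixing ratio outside the validated experimental range."""


class MoistureDomainError(ValueError):
    """Fuel moisture must be strictly positive (% of dry mass)."""


class BareGroundError(ValueError):
    """Raised when a vegetation-weighted average is requested on bare ground.

    Callers must treat the cell as non-flammable rather than propagate NaN.
    """


def _check_oxygen(ox) -> np.ndarray | float:
    ox = np.asarray(ox, dtype=float)
    if np.any(ox < OX_MIN) or np.any(ox > OX_MAX):
        raise OxygenRangeError(
            f"oxygen mixing ratio outside validated range "
            f"[{OX_MIN}, {OX_MAX}] % vol."
        )
    return ox


def _check_moisture(m) -> np.ndarray | float:
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0.0) or not np.all(np.isfinite(m)):
        raise MoistureDomainError("fuel moisture must be finite and > 0 % dry mass")
    return m


def _pi_slope(ox):
    # coefficient of ln(M): cubic in oxygen
    return 308.02 - 27.406 * ox + 0.634 * ox**2 - 0.0044 * ox**3


def _pi_intercept(ox):
    return -633.54 + 42.327 * ox - 0.2194 * ox**2 - 0.0075 * ox**3


def probability_of_ignition(ox, m, *, clamp: bool = True):
    """Probability-of-ignition rating PI(Ox, M), % in [0, 100].

    Empirical regression from bench combustion experiments: a rating of the
    likelihood that a lightning stroke ignites dead fine fuel of moisture
    content ``m`` (% dry mass) at oxygen mixing ratio ``ox`` (% vol.).

    The raw regression can leave [0, 100] at extreme argument pairs; it is a
    probability rating, so the result is clamped to [0, 100] unless
    ``clamp=False`` is passed (used internally and by tests).
    """
    ox = _check_oxygen(ox)
    m = _check_moisture(m)
    pi = _pi_slope(ox) * np.log(m) + _pi_intercept(ox)
    if clamp:
        pi = np.clip(pi, 0.0, 100.0)
    return pi if pi.ndim else float(pi)


def moisture_cap(pi_floor: float = 1.0) -> float:
    """Largest usable moisture for the ignition-scaling normalisation.

    Solves PI(PAL, m_cap) = ``pi_floor`` in closed form.  At PAL the rating
    reaches zero near 22 % moisture; beyond that the normalising denominator
    of the oxygen scaling would vanish, so moisture arguments are capped at
    m_cap (where the rating still equals ``pi_floor`` %) in both numerator
    and denominator.
    """
    a = _pi_slope(OX_PAL)   # negative: rating falls with moisture
    b = _pi_intercept(OX_PAL)
    return math.exp((pi_floor - b) / a)


class IgnitionScaler:
    """Precomputed oxygen scaling of ignition efficiency at one O2 level.

    Calling the scaler with a fuel moisture (scalar or array, % dry mass)
    returns PI(ox, m)/PI(PAL, m) with the moisture cap applied; the
    polynomial coefficients are evaluated once at construction, which
    matters inside the daily simulation loop.
    """

    def __init__(self, ox: float, pi_floor: float = 1.0):
        _check_oxygen(ox)
        self.ox = float(ox)
        self.m_cap = moisture_cap(pi_floor)
        self._a_ox = _pi_slope(self.ox)
        self._b_ox = _pi_intercept(self.ox)
        self._a_pal = _pi_slope(OX_PAL)
        self._b_pal = _pi_intercept(OX_PAL)

    def __call__(self, m):
        lm = np.log(np.minimum(np.asarray(m, dtype=float), self.m_cap))
        num = np.clip(self._a_ox * lm + self._b_ox, 0.0, 100.0)
        den = np.clip(self._a_pal * lm + self._b_pal, 0.0, 100.0)
        s = num / den
        return s if s.ndim else float(s)


def ignition_scaling(ox, m, *, pi_floor: float = 1.0):
    """Oxygen scaling factor for ignition efficiency, PI(ox, m)/PI(PAL, m).

    Applied with fine-fuel/live-grass moisture (omega_nl) for grass fuels and
    with woody fuel moisture (omega_o) for woody fuels.  Exactly 1 at
    ox = PAL for any valid moisture.  For moistures beyond the PAL ignition
    range the ratio is evaluated at the capped moisture (see
    :func:`moisture_cap`), keeping the factor finite and continuous.
    """
    ox = _check_oxygen(ox)
    m = _check_moisture(m)
    lm = np.log(np.minimum(m, moisture_cap(pi_floor)))
    num = np.clip(_pi_slope(ox) * lm + _pi_intercept(ox), 0.0, 100.0)
    den = np.clip(_pi_slope(OX_PAL) * lm + _pi_intercept(OX_PAL), 0.0, 100.0)
    s = num / den
    return s if s.ndim else float(s)


def scale_pft_ignition(ieff_pft, is_grass, s_grass, s_woody):
    """Scale prescribed per-PFT ignition efficiencies by the oxygen factors.

    ``is_grass`` is a boolean (array); grass PFTs are multiplied by the
    grass-fuel factor, tree PFTs by the woody-fuel factor.
    """
    ieff_pft = np.asarray(ieff_pft, dtype=float)
    if np.any(ieff_pft < 0.0) or np.any(ieff_pft > 1.0):
        raise ValueError("base ignition efficiency must lie in [0, 1]")
    if np.any(np.asarray(s_grass) < 0.0) or np.any(np.asarray(s_woody) < 0.0):
        raise ValueError("scaling factors must be >= 0")
    out = np.where(np.asarray(is_grass, dtype=bool), ieff_pft * s_grass, ieff_pft * s_woody)
    return out if out.ndim else float(out)


def fpc_weighted_average(fpc, values, axis=None):
    """Average a per-PFT quantity weighted by foliar projective cover.

    Used both for the cell-mean ignition efficiency and the cell-mean heat
    of combustion.  Raises :class:`BareGroundError` when total cover is zero
    (for array input, when it is zero everywhere along ``axis``).
    """
    fpc = np.asarray(fpc, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(fpc < 0.0):
        raise ValueError("FPC weights must be >= 0")
    total = fpc.sum(axis=axis)
    if np.all(np.asarray(total) == 0.0):
        raise BareGroundError("total FPC is zero: bare ground, cell non-flammable")
    w = (fpc * values).sum(axis=axis) / total
    return w if np.ndim(w) else float(w)


def overall_ignition_efficiency(fdi, ieff_avg, ieff_bf):
    """Overall ignition efficiency: the exact product FDI * ieff_avg * ieff_bf.

    Not capped: the vegetation-mean factor is a ratio and can exceed 1 at
    high oxygen; the product enters an expected-count ignition rate where
    that is meaningful.
    """
    fdi = np.asarray(fdi, dtype=float)
    ieff_avg = np.asarray(ieff_avg, dtype=float)
    ieff_bf = np.asarray(ieff_bf, dtype=float)
    for name, v in (("fdi", fdi), ("ieff_avg", ieff_avg), ("ieff_bf", ieff_bf)):
        if np.any(v < 0.0) or not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite and >= 0")
    out = fdi * ieff_avg * ieff_bf
    return out if out.ndim else float(out)


def moisture_of_extinction(ox):
    """Moisture of extinction Me = 8*Ox - 128, % of dry mass.

    The fuel moisture above which a spreading fire cannot be sustained,
    rising linearly with oxygen; zero at 16 % vol. O2 (dry fuel will not
    carry fire below the lower edge of the fire window).  Values above 100 %
    at high oxygen are legitimate on a dry-mass basis.
    """
    ox = _check_oxygen(ox)
    me = 8.0 * ox - 128.0
    return me if me.ndim else float(me)


def moisture_extinction_scaling(ox):
    """Me(ox)/Me(PAL): multiplies each fuel class's native moisture of
    extinction in the spread model.  Exactly 1 at PAL."""
    ox = _check_oxygen(ox)
    s = moisture_of_extinction(ox) / moisture_of_extinction(OX_PAL)
    return s if np.ndim(s) else float(s)


def pft_heat_of_combustion(ox, alpha, beta):
    """Heat of combustion for a PFT: h = alpha/Ox + beta, kJ/kg.

    ``beta`` is the asymptotic (complete-combustion) heat; ``alpha`` is
    negative for realistic fuels so that heat released rises toward ``beta``
    with increasing oxygen.  The cell mean via :func:`fpc_weighted_average`
    replaces a single fixed heat-of-combustion constant.
    """
    ox = np.asarray(ox, dtype=float)
    if np.any(ox <= 0.0):
        raise OxygenRangeError("oxygen mixing ratio must be positive")
    h = np.asarray(alpha, dtype=float) / ox + np.asarray(beta, dtype=float)
    if np.any(h <= 0.0):
        raise ValueError(
            "non-positive heat of combustion: alpha/beta coefficients inconsistent"
        )
    return h if h.ndim else float(h)
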