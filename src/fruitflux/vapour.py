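"""Physical conversions for water-vapour transport from fruit surfaces.

All quantities use the field conventions of gravimetric fruit studies:
areas in cm^2, molar flux densities in mmol cm^-2 h^-1, pressures in Pa.
No internal SI conversion is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ClampWarning, DomainError, ValidationError

#: Standard sea-level atmospheric pressure, Pa (default; site value unknown).
STANDARD_PRESSURE_PA = 101325.0

#: Molar mass of water, g mol^-1.
WATER_MOLAR_MASS = 18.015

#: Default fruit surface-area coefficients (intercept cm^2, slope unitless),
#: from a planimeter regression on Hayward kiwifruit skins.
AREA_INTERCEPT_CM2 = 0.798
AREA_SLOPE = 1.0078


@dataclass(frozen=True)
class FruitGeometry:
    """Fruit dimensions (cm) and the derived skin surface area (cm^2)."""

    length: float
    width: float
    a_coef: float = AREA_INTERCEPT_CM2
    b_coef: float = AREA_SLOPE

    @property
    def area(self) -> float:
        return fruit_surface_area(self.length, self.width, self.a_coef, self.b_coef)


@dataclass(frozen=True)
class VapourGap:
    """Vapour pressures (Pa) across the fruit skin and their mol-fraction gap.

    Assumes the fruit's internal air spaces are water saturated (p_i = p at
    air temperature) and that fruit temperature equals air temperature.
    """

    p: float
    p_i: float
    p_a: float
    P: float

    @property
    def delta_pw(self) -> float:
        return (self.p_i - self.p_a) / self.P


def saturated_vapour_pressure(T):
    """Saturated vapour pressure of water (Pa) at air temperature ``T`` (degC).

    Uses the exponential approximation 610.7 * exp(17.4*T / (239 + T)),
    valid for ordinary meteorological temperatures; strictly increasing in T.

    Parameters
    ----------
    T : float or array_like
        Air temperature in degrees Celsius. Must exceed -239.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= -239.0):
        raise DomainError("temperature must exceed -239 degC (denominator 239 + T)")
    out = 610.7 * np.exp(17.4 * T / (239.0 + T))
    return out if out.ndim else float(out)


def validate_rh(RH, clamp_max: float = 102.0):
    """Validate relative humidity in percent, clamping mild sensor overshoot.

    Values in (100, ``clamp_max``] are clamped to 100 with a warning; values
    below 0 or above ``clamp_max`` raise :class:`ValidationError`.
    """
    RH = np.asarray(RH, dtype=float)
    if np.any(RH < 0.0) or np.any(RH > clamp_max):
        bad = RH[(RH < 0.0) | (RH > clamp_max)]
        raise ValidationError(
            f"relative humidity outside [0, {clamp_max}] %: {np.atleast_1d(bad)[:5]}"
        )
    if np.any(RH > 100.0):
        warnings.warn(
            "relative humidity in (100, 102] % clamped to 100 %", ClampWarning,
            stacklevel=2,
        )
        RH = np.minimum(RH, 100.0)
    return RH if RH.ndim else float(RH)


def delta_pw(T, RH, P=STANDARD_PRESSURE_PA):
    """Dimensionless mol-fraction vapour difference driving transpiration.

    Computes (p_i - p_a) / P with p_i = saturated vapour pressure at ``T``
    and p_a = p_i * RH/100, i.e. p * (1 - RH/100) / P. Zero exactly at
    RH = 100; always non-negative.

    Parameters
    ----------
    T : air temperature, degC.
    RH : relative humidity, percent, in [0, 100] after validation.
    P : atmospheric pressure, Pa (default standard sea level).
    """
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0.0):
        raise DomainError("atmospheric pressure must be positive")
    RH = validate_rh(RH)
    p = saturated_vapour_pressure(T)
    out = np.asarray(p) * (1.0 - np.asarray(RH) / 100.0) / P
    return out if out.ndim else float(out)


def fruit_surface_area(length, width, a_coef=AREA_INTERCEPT_CM2, b_coef=AREA_SLOPE):
    """Fruit skin surface area (cm^2) from length and maximum width (cm).

    A = a + b * pi * length * width.
    """
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(length <= 0.0) or np.any(width <= 0.0):
        raise ValidationError("fruit length and width must be positive")
    out = a_coef + b_coef * np.pi * length * width
    return out if out.ndim else float(out)


def weight_loss_to_flux(w_start, w_end, dt, area, molar_mass=WATER_MOLAR_MASS):
    """Convert a gravimetric weight loss to a molar flux density.

    Parameters
    ----------
    w_start, w_end : fruit weight at interval start/end, g.
    dt : interval duration, h.
    area : fruit surface area, cm^2.
    molar_mass : molar mass of water, g mol^-1.

    Returns
    -------
    Transpiration rate E in mmol cm^-2 h^-1. May be negative for noisy
    records (apparent weight gain); filtering is the caller's decision.
    """
    dt = np.asarray(dt, dtype=float)
    area = np.asarray(area, dtype=float)
    if np.any(dt <= 0.0):
        raise DomainError("interval duration must be positive")
    if np.any(area <= 0.0):
        raise DomainError("fruit surface area must be positive")
    loss = np.asarray(w_start, dtype=float) - np.asarray(w_end, dtype=float)
    out = loss / molar_mass * 1000.0 / (area * dt)
    return out if out.ndim else float(out)
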