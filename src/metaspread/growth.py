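"""Gompertzian primary-tumor growth and diameter -> tumor-age imputation.

The primary tumor volume follows the Gompertz law

    V(t) = V(0) * exp((alpha/beta) * (1 - exp(-beta * t))),

with ``t`` in days since initiation (a single cell), ``alpha`` the initial
instantaneous growth rate and ``beta`` the exponential decay rate of the
growth rate.  Tumors are treated as spheres throughout, so volume, diameter
and cell count interconvert via the cube of the diameter ratio.  Defaults
(alpha = 0.0359 /day, beta = 0.0013 /day, initial cell diameter 10 um) put
the asymptotic diameter just under the 100 mm diameter (~1e12 cells)
conventionally taken as lethal.

Tumor age is imputed by inverting the growth law at the recorded diameter;
years are 365 days throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.0

#: relative clamp applied to diameters at/above the Gompertz asymptote
_ASYMPTOTE_CLAMP = 1.0 - 1e-6


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz growth-law parameters.

    alpha_per_day
        Initial instantaneous growth rate (1/day).
    beta_per_day
        Exponential decay rate of the growth rate (1/day).
    d0_um
        Diameter of the initiating single cell (micrometres).
    d_lethal_mm
        Lethal diameter (millimetres); with the default alpha the Gompertz
        asymptote sits just below it.
    """

    alpha_per_day: float = 0.0359
    beta_per_day: float = 0.0013
    d0_um: float = 10.0
    d_lethal_mm: float = 100.0

    def __post_init__(self) -> None:
        if self.alpha_per_day <= 0 or self.beta_per_day <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.d0_um <= 0:
            raise ValueError("initial cell diameter must be positive")
        if self.d_lethal_mm * 1000.0 <= self.d0_um:
            raise ValueError("lethal diameter must exceed the initial diameter")

    @property
    def d0_mm(self) -> float:
        return self.d0_um / 1000.0

    @property
    def v0_um3(self) -> float:
        """Volume of the initiating cell (um^3), spherical."""
        return (np.pi / 6.0) * self.d0_um**3

    @property
    def asymptotic_diameter_mm(self) -> float:
        """Diameter the Gompertz curve approaches as t -> infinity."""
        return self.d0_mm * np.exp(self.alpha_per_day / (3.0 * self.beta_per_day))


def volume_at_age(t_days, p: GompertzParams = GompertzParams()):
    """Tumor volume (um^3) at ``t_days`` since initiation."""
    t = np.asarray(t_days, dtype=float)
    if np.any(t < 0):
        raise ValueError("tumor age must be non-negative")
    a, b = p.alpha_per_day, p.beta_per_day
    v = p.v0_um3 * np.exp((a / b) * (1.0 - np.exp(-b * t)))
    return v if v.ndim else float(v)


def diameter_at_age(t_days, p: GompertzParams = GompertzParams()):
    """Tumor diameter (mm) at ``t_days`` since initiation."""
    v = np.asarray(volume_at_age(t_days, p))
    d_um = (6.0 * v / np.pi) ** (1.0 / 3.0)
    d = d_um / 1000.0
    return d if d.ndim else float(d)


def diameter_to_age(d_mm, p: GompertzParams = GompertzParams(), clamp: bool = True):
    """Tumor age in YEARS for a tumor of diameter ``d_mm``.

    Exact inverse of the growth law:

        t_days = -(1/beta) * ln(1 - (beta/alpha) * 3 * ln(d/d0)).

    Diameters at or above the Gompertz asymptote (which the <=100 mm
    inclusion filter can admit) have no finite preimage; with
    ``clamp=True`` the log-volume ratio is clamped just below the asymptote,
    yielding a large finite age, and a warning is logged with the count.
    Diameters <= d0 raise.
    """
    d = np.asarray(d_mm, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if np.any(d <= p.d0_mm):
        raise ValueError(
            f"diameter must exceed the initial cell diameter ({p.d0_mm} mm)"
        )
    a, b = p.alpha_per_day, p.beta_per_day
    x = 3.0 * np.log(d / p.d0_mm)  # ln(V/V0)
    limit = a / b
    over = x >= limit * _ASYMPTOTE_CLAMP
    if np.any(over):
        if not clamp:
            raise ValueError(
                "diameter at or above the Gompertz asymptote "
                f"({p.asymptotic_diameter_mm:.2f} mm) has no finite age"
            )
        logger.warning(
            "%d diameter(s) at/above the Gompertz asymptote (%.2f mm); "
            "age clamped to the near-asymptotic value",
            int(over.sum()),
            p.asymptotic_diameter_mm,
        )
        x = np.where(over, limit * _ASYMPTOTE_CLAMP, x)
    t_days = -(1.0 / b) * np.log(1.0 - (b / a) * x)
    t_years = t_days / DAYS_PER_YEAR
    return float(t_years[0]) if scalar else t_years


def cell_count(d_mm, d0_um: float = 10.0):
    """Number of cells in a tumor of diameter ``d_mm``.

    Spherical volume divided by the single-cell volume: ``(d/d0)**3``.
    A 100 mm tumor with a 10 um cell is 1e12 cells.
    """
    d = np.asarray(d_mm, dtype=float)
    d0_mm = d0_um / 1000.0
    if np.any(d < d0_mm):
        raise ValueError("diameter below the single-cell diameter")
    n = (d / d0_mm) ** 3
    return n if n.ndim else float(n)


def calibrate_alpha(beta_per_day: float, d0_um: float, d_lethal_mm: float) -> float:
    """alpha (1/day) making the Gompertz asymptote equal the lethal diameter.

    From V(inf) = V0 * exp(alpha/beta):  alpha = beta * 3 * ln(d_lethal/d0).
    """
    if beta_per_day <= 0 or d0_um <= 0 or d_lethal_mm <= 0:
        raise ValueError("inputs must be positive")
    return beta_per_day * 3.0 * np.log(d_lethal_mm * 1000.0 / d0_um)


def time_to_lethal_constant_doubling(
    doubling_time_days: float = 150.0, n_lethal: float = 1e12
) -> float:
    """Years from one cell to ``n_lethal`` cells at a constant doubling time."""
    if doubling_time_days <= 0:
        raise ValueError("doubling time must be positive")
    if n_lethal < 1:
        raise ValueError("lethal cell count must be >= 1")
    return float(np.log2(n_lethal) * doubling_time_days / DAYS_PER_YEAR)
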