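"""Flory-Huggins miscibility from melting-point depression.

A crystalline drug dissolved in a polymer melts below its pure melting
point; within Flory-Huggins lattice theory the depression obeys

    1/Tm_mix - 1/Tm_pure =
        (-R / dHfus) * [ln(phi_d) + (1 - 1/m) phi_p + chi phi_p^2]

where phi_d, phi_p are the drug and polymer volume fractions, m is the
polymer-to-drug molar-volume ratio, dHfus the molar fusion enthalpy of the
pure drug and chi the interaction parameter.  Rearranged, plotting

    y = (1/Tm_mix - 1/Tm_pure) * (dHfus / -R) - ln(phi_d) - (1 - 1/m) phi_p

against x = phi_p^2 is a line through the origin with slope chi (treated as
temperature-independent at low polymer fractions).  chi < 0 signals
favourable drug-polymer contacts, i.e. thermodynamic miscibility.

The mixing free energy per lattice site follows the standard FH form

    dG_mix/RT = phi_d ln(phi_d) + (phi_p / m) ln(phi_p) + chi phi_d phi_p

which is strictly negative at every composition when chi <= 0 and m >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import R_GAS
from .errors import DegenerateFitError, DomainError, InsufficientDataError

__all__ = [
    "MeltingDepressionSeries",
    "FHFit",
    "MixingFreeEnergyCurve",
    "fh_linearized_points",
    "fit_chi",
    "mixing_free_energy_curve",
    "volume_fractions_from_weights",
]


@dataclass(frozen=True)
class MeltingDepressionSeries:
    """Melting points of drug-polymer mixtures versus polymer volume fraction.

    Temperatures are kelvin throughout; use ``from_celsius`` for instrument
    exports in degrees C (the conversion happens exactly once, here).
    """

    tm_pure: float               # K, pure-drug melting point
    dhfus: float                 # J/mol, pure-drug fusion enthalpy
    m: float                     # polymer/drug molar-volume ratio (dimensionless)
    points: tuple[tuple[float, float], ...]   # (phi_polymer, tm_mix [K])

    def __post_init__(self) -> None:
        if self.tm_pure <= 0:
            raise DomainError("tm_pure must be positive (kelvin)")
        if self.dhfus <= 0:
            raise DomainError("dhfus must be positive")
        if self.m < 1:
            raise DomainError("m (polymer/drug volume ratio) must be >= 1")
        phis = [p for p, _ in self.points]
        if any(not (0.0 < p < 1.0) for p in phis):
            raise DomainError("polymer volume fractions must lie strictly in (0, 1)")
        if len(set(phis)) != len(phis):
            raise DomainError("polymer volume fractions must be distinct")
        if any(t <= 0 for _, t in self.points):
            raise DomainError("mixture melting points must be positive (kelvin)")

    @classmethod
    def from_celsius(cls, tm_pure_c: float, dhfus: float, m: float,
                     points_c: Sequence[tuple[float, float]]) -> "MeltingDepressionSeries":
        from .constants import celsius_to_kelvin as c2k
        return cls(c2k(tm_pure_c), dhfus, m,
                   tuple((phi, c2k(t)) for phi, t in points_c))


@dataclass(frozen=True)
class FHFit:
    chi: float
    r_squared: float
    n_points: int
    intercept: float


@dataclass(frozen=True)
class MixingFreeEnergyCurve:
    phi_drug: np.ndarray     # strictly increasing grid in (0, 1)
    dg_over_rt: np.ndarray   # dimensionless, same length
    chi: float
    m: float


def fh_linearized_points(series: MeltingDepressionSeries) -> list[tuple[float, float]]:
    """Map each (phi_polymer, Tm_mix) to the (x, y) of the chi regression.

    x = phi_polymer^2 and y collects every term of the depression equation
    except chi*x, so a perfect FH system gives y = chi * x exactly.
    """
    out = []
    for phi_p, tm_mix in series.points:
        phi_d = 1.0 - phi_p
        y = ((1.0 / tm_mix - 1.0 / series.tm_pure) * (series.dhfus / -R_GAS)
             - np.log(phi_d) - (1.0 - 1.0 / series.m) * phi_p)
        out.append((phi_p ** 2, float(y)))
    return out


def fit_chi(series: MeltingDepressionSeries,
            fit_window: slice | None = None) -> FHFit:
    """Estimate chi as the OLS slope of the linearized depression plot.

    ``fit_window`` optionally restricts which points (ordered as supplied)
    enter the regression; the default uses all of them.  The intercept is
    reported for diagnostics but carries no FH meaning (an ideal system has
    intercept 0).
    """
    pts = fh_linearized_points(series)
    if fit_window is not None:
        pts = pts[fit_window]
    if len(pts) < 2:
        raise InsufficientDataError("chi fit needs at least 2 depression points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in phi_polymer^2; cannot fit a slope")
    res = stats.linregress(x, y)
    return FHFit(chi=float(res.slope), r_squared=float(res.rvalue ** 2),
                 n_points=len(pts), intercept=float(res.intercept))


def mixing_free_energy_curve(chi: float, m: float,
                             grid: Sequence[float] | np.ndarray) -> MixingFreeEnergyCurve:
    """Evaluate dG_mix/RT on a drug-volume-fraction grid in the open (0, 1)."""
    if m < 1:
        raise DomainError("m must be >= 1")
    phi_d = np.asarray(grid, dtype=float)
    if phi_d.ndim != 1 or len(phi_d) == 0:
        raise DomainError("grid must be a non-empty 1-D sequence")
    if np.any(phi_d <= 0.0) or np.any(phi_d >= 1.0):
        raise DomainError("grid must lie strictly inside (0, 1)")
    if np.any(np.diff(phi_d) <= 0):
        raise DomainError("grid must be strictly increasing")
    phi_p = 1.0 - phi_d
    dg = phi_d * np.log(phi_d) + (phi_p / m) * np.log(phi_p) + chi * phi_d * phi_p
    return MixingFreeEnergyCurve(phi_d, dg, chi, m)


def volume_fractions_from_weights(w_drug: float, density_drug: float,
                                  density_polymer: float) -> tuple[float, float]:
    """Convert a drug weight fraction to (phi_drug, phi_polymer)."""
    if density_drug <= 0 or density_polymer <= 0:
        raise DomainError("densities must be positive")
    if not (0.0 <= w_drug <= 1.0):
        raise DomainError("weight fraction must be in [0, 1]")
    vd = w_drug / density_drug
    vp = (1.0 - w_drug) / density_polymer
    phi_d = vd / (vd + vp)
    return phi_d, 1.0 - phi_d
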