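"""Dissolution and solvent-shift profile metrics.

Supersaturating formulations (amorphous dispersions, precipitation
inhibitors) are compared on a small set of profile summaries: the peak
dissolved concentration c_max and its time t_max, the trapezoidal area
under the concentration-time curve (AUC), the maximum supersaturation
ratio c_max / Cs against the crystalline equilibrium solubility Cs, the
precipitation retention (final concentration / c_max, 1 means no decline),
and the fold enhancement of c_max over a reference profile (e.g. the
crystalline drug).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError

__all__ = [
    "ConcentrationProfile",
    "DissolutionMetrics",
    "profile_metrics",
    "compare_inhibitors",
]


@dataclass(frozen=True)
class ConcentrationProfile:
    """Dissolved-drug concentration (ug/mL) at strictly increasing times (min)."""

    sample_id: str
    times: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.concentrations):
            raise DomainError(f"{self.sample_id}: times/concentrations length mismatch")
        if len(self.times) < 2:
            raise InsufficientDataError(f"{self.sample_id}: need at least 2 points")
        if self.times[0] < 0:
            raise DomainError(f"{self.sample_id}: times must start at >= 0")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise DomainError(f"{self.sample_id}: times must be strictly increasing")
        if any(c < 0 for c in self.concentrations):
            raise DomainError(f"{self.sample_id}: concentrations must be >= 0")

    def resampled(self, grid: Sequence[float]) -> "ConcentrationProfile":
        """Linear interpolation onto ``grid``; no extrapolation allowed."""
        g = np.asarray(grid, dtype=float)
        if g[0] < self.times[0] - 1e-12 or g[-1] > self.times[-1] + 1e-12:
            raise DomainError(f"{self.sample_id}: grid extends beyond observed window")
        c = np.interp(g, self.times, self.concentrations)
        return ConcentrationProfile(self.sample_id, tuple(g), tuple(c))


@dataclass(frozen=True)
class DissolutionMetrics:
    c_max: float                     # ug/mL
    t_max: float                     # min, earliest time attaining c_max
    auc: float                       # ug min / mL, trapezoidal
    supersaturation_max: float       # c_max / Cs
    retention: float                 # final concentration / c_max, in [0, 1]
    fold_vs_reference: float | None  # c_max / c_max(reference)


def profile_metrics(profile: ConcentrationProfile, cs: float,
                    reference: ConcentrationProfile | None = None) -> DissolutionMetrics:
    """Summary metrics of one profile against equilibrium solubility ``cs``.

    An all-zero profile has retention defined as 0; requesting a fold
    against an all-zero reference is an error (undefined ratio).
    """
    if cs <= 0:
        raise DomainError("equilibrium solubility cs must be positive")
    t = np.asarray(profile.times)
    c = np.asarray(profile.concentrations)
    c_max = float(c.max())
    t_max = float(t[int(np.argmax(c))])
    auc = float(np.trapezoid(c, t))
    retention = float(c[-1] / c_max) if c_max > 0 else 0.0
    fold = None
    if reference is not None:
        ref_max = max(reference.concentrations)
        if ref_max == 0:
            raise DomainError("fold undefined: reference profile is all zero")
        fold = c_max / ref_max
    return DissolutionMetrics(c_max, t_max, auc, c_max / cs, retention, fold)


def compare_inhibitors(profiles: Mapping[str, ConcentrationProfile],
                       cs: float = 1.0) -> list[dict]:
    """Rank candidate precipitation inhibitors.

    Profiles are resampled by linear interpolation onto the intersection of
    their time windows (union of all sampling instants inside it), then
    ranked by retention, ties broken by AUC, then lexically by sample id.
    Exact retention-and-AUC ties are flagged.
    """
    if len(profiles) < 2:
        raise InsufficientDataError("inhibitor comparison needs at least 2 profiles")
    t_lo = max(p.times[0] for p in profiles.values())
    t_hi = min(p.times[-1] for p in profiles.values())
    if t_hi <= t_lo:
        raise DomainError("profiles share no common time window")
    grid = sorted({t for p in profiles.values() for t in p.times if t_lo <= t <= t_hi})
    rows = []
    for sid in sorted(profiles):
        m = profile_metrics(profiles[sid].resampled(grid), cs)
        rows.append({"sample_id": sid, "retention": m.retention, "auc": m.auc,
                     "c_max": m.c_max, "tie": False})
    rows.sort(key=lambda r: (-r["retention"], -r["auc"], r["sample_id"]))
    for a, b in zip(rows, rows[1:]):
        if a["retention"] == b["retention"] and a["auc"] == b["auc"]:
            a["tie"] = b["tie"] = True
    for rank, r in enumerate(rows, start=1):
        r["rank"] = rank
    return rows
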