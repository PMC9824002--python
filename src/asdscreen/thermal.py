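"""DSC and TGA interpretation: glass-forming ability, single-Tg miscibility
verdicts, and thermogravimetric water-loss / decomposition summaries.

Glass-forming ability (GFA) follows the heat-cool-heat classification:
a compound that recrystallizes while cooling from the melt is a class I
(non-glass former); one that stays amorphous on cooling but recrystallizes
on reheating is class II (non-stable glass former); one that never
recrystallizes, even through the second heating, is class III (stable
glass former).  Inputs are picked event lists, not raw heat-flow curves --
peak picking is instrument-specific; a deliberately simple prominence-based
finder is provided as a labelled heuristic convenience only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError

__all__ = [
    "EventKind",
    "ThermalEvent",
    "DSCCycle",
    "GFAClass",
    "TGATrace",
    "classify_gfa",
    "tg_miscibility_verdict",
    "analyze_tga",
    "pick_events_heuristic",
]


class EventKind(str, Enum):
    melting_endotherm = "melting_endotherm"
    crystallization_exotherm = "crystallization_exotherm"
    glass_transition = "glass_transition"


@dataclass(frozen=True)
class ThermalEvent:
    """One picked DSC event: kind, peak/midpoint temperature (C), enthalpy (J/g)."""

    kind: EventKind
    temperature_c: float
    enthalpy_j_g: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.temperature_c):
            raise DomainError("event temperature must be finite")
        if self.enthalpy_j_g < 0:
            raise DomainError("event enthalpy must be non-negative")


@dataclass(frozen=True)
class DSCCycle:
    """Events of a heat-cool-heat scan, each segment ordered along its scan."""

    heat1: tuple[ThermalEvent, ...] = ()
    cool: tuple[ThermalEvent, ...] = ()
    heat2: tuple[ThermalEvent, ...] = ()


class GFAClass(str, Enum):
    I = "I"
    II = "II"
    III = "III"


@dataclass(frozen=True)
class TGATrace:
    """Weight-versus-temperature trace, weight as % of initial mass."""

    points: tuple[tuple[float, float], ...]   # (temperature C, weight %)

    def __post_init__(self) -> None:
        temps = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise DomainError("TGA temperatures must be strictly increasing")
        if any(w < 0 or w > 101.0 for _, w in self.points):
            raise DomainError("weight_percent out of [0, 101]")


def _has(events: Sequence[ThermalEvent], kind: EventKind) -> bool:
    return any(e.kind is kind for e in events)


def classify_gfa(cycle: DSCCycle) -> GFAClass:
    """Classify glass-forming ability from a heat-cool-heat event sequence.

    Requires a melting endotherm in the first heating (the melt must have
    been reached, otherwise the protocol is not assessable).  A cooling
    exotherm dominates: it yields class I regardless of reheating content.
    """
    if not _has(cycle.heat1, EventKind.melting_endotherm):
        raise InsufficientDataError(
            "GFA not assessable: no melting endotherm in the first heating"
        )
    if _has(cycle.cool, EventKind.crystallization_exotherm):
        return GFAClass.I
    if _has(cycle.heat2, EventKind.crystallization_exotherm):
        return GFAClass.II
    return GFAClass.III


TgVerdict = Literal["miscible_single_tg", "phase_separated", "indeterminate"]


def tg_miscibility_verdict(tg_temperatures_c: Sequence[float],
                           tolerance_c: float = 2.0) -> TgVerdict:
    """Single-Tg miscibility check.

    Tgs closer than ``tolerance_c`` are merged (instrument repeatability);
    one merged Tg means the blend relaxes as a single phase, two or more
    separated Tgs mean phase separation, no Tg at all is indeterminate.
    """
    if tolerance_c < 0:
        raise DomainError("tolerance must be non-negative")
    tgs = sorted(tg_temperatures_c)
    if not tgs:
        return "indeterminate"
    clusters = 1
    for a, b in zip(tgs, tgs[1:]):
        if b - a > tolerance_c:
            clusters += 1
    return "miscible_single_tg" if clusters == 1 else "phase_separated"


def analyze_tga(trace: TGATrace, early_cutoff_c: float = 120.0,
                loss_threshold_pct: float = 2.0) -> tuple[float, float | None]:
    """Initial (water) loss and decomposition onset from a TGA trace.

    initial_loss is 100 minus the (linearly interpolated) weight at
    ``early_cutoff_c``; the onset is the first temperature past the cutoff
    at which the weight has dropped ``loss_threshold_pct`` below that early
    plateau, located by interpolation, or None if the trace never does.
    """
    if len(trace.points) < 3:
        raise InsufficientDataError("TGA analysis needs at least 3 points")
    temps = np.array([t for t, _ in trace.points])
    weights = np.array([w for _, w in trace.points])
    if not (temps[0] <= early_cutoff_c <= temps[-1]):
        raise DomainError(
            f"early_cutoff {early_cutoff_c} C outside trace range "
            f"[{temps[0]}, {temps[-1]}] C"
        )
    w_cut = float(np.interp(early_cutoff_c, temps, weights))
    initial_loss = 100.0 - w_cut

    target = w_cut - loss_threshold_pct
    after = temps >= early_cutoff_c
    t_aft = np.concatenate(([early_cutoff_c], temps[after]))
    w_aft = np.concatenate(([w_cut], weights[after]))
    below = np.nonzero(w_aft < target)[0]
    if below.size == 0:
        return initial_loss, None
    i = below[0]          # first sample below the threshold; crossing is in (i-1, i]
    t0, t1 = t_aft[i - 1], t_aft[i]
    w0, w1 = w_aft[i - 1], w_aft[i]
    onset = t0 + (w0 - target) * (t1 - t0) / (w0 - w1)
    return initial_loss, float(onset)


def pick_events_heuristic(temperature_c: Sequence[float],
                          heat_flow: Sequence[float],
                          prominence: float = 0.1) -> list[ThermalEvent]:
    """Heuristic peak picker for raw heat-flow segments (convenience only).

    Positive peaks (exotherm-up convention) become crystallization
    exotherms, negative peaks melting endotherms; no enthalpy integration
    or Tg-step detection is attempted.  Prefer instrument-software event
    lists for real analyses.
    """
    from scipy.signal import find_peaks

    t = np.asarray(temperature_c, dtype=float)
    hf = np.asarray(heat_flow, dtype=float)
    events: list[ThermalEvent] = []
    up, _ = find_peaks(hf, prominence=prominence)
    for i in up:
        events.append(ThermalEvent(EventKind.crystallization_exotherm, float(t[i])))
    down, _ = find_peaks(-hf, prominence=prominence)
    for i in down:
        events.append(ThermalEvent(EventKind.melting_endotherm, float(t[i])))
    events.sort(key=lambda e: e.temperature_c)
    return events
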