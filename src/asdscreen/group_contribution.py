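"""Hansen solubility parameters by the Hoftyzer-Van Krevelen group-contribution
method, and the Greenhalgh total-parameter miscibility rule.

The HVK scheme assigns each structural group three cohesive increments --
a dispersion attraction constant ``Fdi`` (J^1/2 cm^3/2 mol^-1/2), a polar
attraction constant ``Fpi`` (same units) and a hydrogen-bonding cohesive
energy ``Ehi`` (J mol^-1) -- plus a Fedors molar-volume increment ``Vi``
(cm^3 mol^-1).  For a molecule (or polymer repeat unit) with group counts
``N_i`` the partial solubility parameters are

    delta_d = sum(N_i Fdi) / V
    delta_p = sqrt(sum(N_i Fpi^2)) / V
    delta_h = sqrt(sum(N_i Ehi) / V)

with V the molar volume, and the total parameter is the Euclidean norm

    delta_t = sqrt(delta_d^2 + delta_p^2 + delta_h^2)

all in MPa^1/2 (J^1/2 cm^-3/2 is numerically identical to MPa^1/2).

Drug-polymer miscibility is then screened on the absolute difference of the
total parameters: blends are likely glassy solid solutions below 2 MPa^1/2,
miscible below 7, immiscible above 10; the unclaimed 7-10 MPa^1/2 interval
is reported as ``borderline`` rather than silently assigned.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import pandas as pd

from .errors import DomainError, ParseError, ResolutionError

__all__ = [
    "GroupValues",
    "GroupTable",
    "GroupInventory",
    "ContributionSums",
    "HansenParameters",
    "MiscibilityVerdict",
    "load_default_group_table",
    "parse_inventory_line",
    "sum_group_contributions",
    "estimate_molar_volume",
    "hansen_from_sums",
    "hansen_from_inventory",
    "total_solubility_parameter",
    "classify_miscibility_delta",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupValues:
    """HVK increments for one structural group.

    Fdi, Fpi in J^1/2 cm^3/2 mol^-1/2; Ehi in J mol^-1; Vi is the Fedors
    molar-volume increment in cm^3 mol^-1 (may be negative for branch
    points such as >CH- or >N-).
    """

    Fdi: float
    Fpi: float
    Ehi: float
    Vi: float

    def __post_init__(self) -> None:
        if self.Fdi < 0 or self.Ehi < 0 or self.Fpi < 0:
            raise DomainError("group attraction constants must be non-negative")


@dataclass(frozen=True)
class GroupTable:
    """Mapping of structural-group labels to their HVK/Fedors increments."""

    groups: Mapping[str, GroupValues]
    version: str = "hvk-fedors-1"

    def __getitem__(self, label: str) -> GroupValues:
        try:
            return self.groups[label]
        except KeyError:
            raise ResolutionError(
                f"unknown structural group label: {label!r} "
                f"(table {self.version} knows {sorted(self.groups)})"
            ) from None

    def __contains__(self, label: str) -> bool:
        return label in self.groups


@dataclass(frozen=True)
class GroupInventory:
    """Per-molecule (or per-monomer) counts of structural groups."""

    species_id: str
    entries: tuple[tuple[str, int], ...]
    basis: Literal["per_molecule", "per_monomer"] = "per_molecule"

    def __post_init__(self) -> None:
        if not self.entries:
            raise DomainError(f"{self.species_id}: inventory has no entries")
        for label, n in self.entries:
            if n < 1 or int(n) != n:
                raise DomainError(
                    f"{self.species_id}: count for {label!r} must be a positive integer"
                )


@dataclass(frozen=True)
class ContributionSums:
    """The three group-contribution sums feeding the HVK relations."""

    sum_NFdi: float      # sum N_i * Fdi
    sum_NFpi2: float     # sum N_i * Fpi^2
    sum_NEhi: float      # sum N_i * Ehi

    def __post_init__(self) -> None:
        if min(self.sum_NFdi, self.sum_NFpi2, self.sum_NEhi) < 0:
            raise DomainError("contribution sums must be non-negative")


@dataclass(frozen=True)
class HansenParameters:
    """Partial and total solubility parameters (MPa^1/2) with molar volume."""

    delta_d: float
    delta_p: float
    delta_h: float
    delta_t: float
    V: float  # cm^3 mol^-1

    def __post_init__(self) -> None:
        if min(self.delta_d, self.delta_p, self.delta_h) < 0:
            raise DomainError("partial solubility parameters must be non-negative")
        norm = math.hypot(self.delta_d, self.delta_p, self.delta_h)
        if not math.isclose(self.delta_t, norm, rel_tol=1e-9, abs_tol=1e-12):
            raise DomainError("delta_t must equal the norm of the partials")


VerdictLabel = Literal["glassy_solid_solution", "miscible", "borderline", "immiscible"]


@dataclass(frozen=True)
class MiscibilityVerdict:
    """Greenhalgh screen on |delta_t(API) - delta_t(polymer)|."""

    delta_delta_t: float
    label: VerdictLabel


# --------------------------------------------------------------------------
# table and inventory I/O
# --------------------------------------------------------------------------

def load_group_table(path) -> GroupTable:
    """Read a group table CSV with columns label, Fdi, Fpi, Ehi, Vi."""
    df = pd.read_csv(path)
    required = {"label", "Fdi", "Fpi", "Ehi", "Vi"}
    if not required.issubset(df.columns):
        raise ParseError(f"group table missing columns {sorted(required - set(df.columns))}")
    if df["label"].duplicated().any():
        dupes = df.loc[df["label"].duplicated(), "label"].tolist()
        raise ParseError(f"duplicate group labels: {dupes}")
    groups = {
        str(row.label): GroupValues(float(row.Fdi), float(row.Fpi), float(row.Ehi), float(row.Vi))
        for row in df.itertuples()
    }
    return GroupTable(groups)


def load_default_group_table() -> GroupTable:
    """The standard Van Krevelen / Fedors increments shipped as package data."""
    with resources.files("asdscreen.data").joinpath("hvk_groups.csv").open("r") as fh:
        return load_group_table(fh)


_TERM_RE = re.compile(r"^\s*(\d+)\s*\*\s*(\S+)\s*$")


def parse_inventory_line(species_id: str, line: str,
                         basis: str = "per_molecule") -> GroupInventory:
    """Parse the one-line grammar ``"4*-OH + 3*=CH- + 1*-CO-"``."""
    entries = []
    for term in line.split("+"):
        m = _TERM_RE.match(term)
        if m is None:
            raise ParseError(f"cannot parse inventory term {term.strip()!r}")
        entries.append((m.group(2), int(m.group(1))))
    return GroupInventory(species_id, tuple(entries), basis)  # type: ignore[arg-type]


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def sum_group_contributions(inventory: GroupInventory, table: GroupTable) -> ContributionSums:
    """Accumulate sum(N Fdi), sum(N Fpi^2) and sum(N Ehi) over the inventory."""
    s_fd = s_fp2 = s_eh = 0.0
    for label, n in inventory.entries:
        g = table[label]
        s_fd += n * g.Fdi
        s_fp2 += n * g.Fpi ** 2
        s_eh += n * g.Ehi
    return ContributionSums(s_fd, s_fp2, s_eh)


def estimate_molar_volume(inventory: GroupInventory, table: GroupTable,
                          override: float | None = None) -> float:
    """Molar volume in cm^3 mol^-1 by Fedors group additivity.

    A caller-supplied ``override`` passes through unchanged; use it when an
    experimentally anchored volume is available (Fedors additivity without
    ring/closure corrections underestimates fused polycyclics).
    """
    if override is not None:
        if override <= 0:
            raise DomainError("molar-volume override must be positive")
        return float(override)
    v = 0.0
    for label, n in inventory.entries:
        v += n * table[label].Vi
    if v <= 0:
        raise DomainError(
            f"{inventory.species_id}: Fedors sum is non-positive ({v:.2f} cm^3/mol); "
            "supply a molar-volume override"
        )
    return v


def hansen_from_sums(sums: ContributionSums, V: float) -> HansenParameters:
    """HVK partial parameters from the contribution sums and molar volume V."""
    if V <= 0:
        raise DomainError("molar volume must be positive")
    delta_d = sums.sum_NFdi / V
    delta_p = math.sqrt(sums.sum_NFpi2) / V
    delta_h = math.sqrt(sums.sum_NEhi / V)
    delta_t = math.hypot(delta_d, delta_p, delta_h)
    return HansenParameters(delta_d, delta_p, delta_h, delta_t, V)


def hansen_from_inventory(inventory: GroupInventory, table: GroupTable,
                          molar_volume: float | None = None) -> HansenParameters:
    """Convenience chain: sums -> molar volume -> Hansen parameters."""
    sums = sum_group_contributions(inventory, table)
    v = estimate_molar_volume(inventory, table, override=molar_volume)
    return hansen_from_sums(sums, v)


def total_solubility_parameter(delta_d: float, delta_p: float, delta_h: float) -> float:
    """Euclidean combination of the three partial parameters."""
    if min(delta_d, delta_p, delta_h) < 0:
        raise DomainError("partial solubility parameters must be non-negative")
    return math.hypot(delta_d, delta_p, delta_h)


def classify_miscibility_delta(delta_t_api: float, delta_t_polymer: float) -> MiscibilityVerdict:
    """Greenhalgh rule on the absolute total-parameter difference.

    < 2 MPa^1/2 glassy solid solution; < 7 miscible; > 10 immiscible;
    the inclusive interval [7, 10] is reported as borderline.
    """
    if delta_t_api < 0 or delta_t_polymer < 0:
        raise DomainError("solubility parameters must be non-negative")
    dd = abs(delta_t_api - delta_t_polymer)
    if dd < 2.0:
        label: VerdictLabel = "glassy_solid_solution"
    elif dd < 7.0:
        label = "miscible"
    elif dd <= 10.0:
        label = "borderline"
    else:
        label = "immiscible"
    return MiscibilityVerdict(dd, label)
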