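"""Synthetic-data generators and the luteolin/PVP reference fixtures.

Each generator emulates the statistical structure one analysis stage
assumes -- melting-point depression consistent with the Flory-Huggins
relation at a chosen true chi, periodic configurations with a planted
number of hydrogen-bond geometries, two-slope specific-volume cooling
curves with a known kink, and first-order dissolution curves with an
optional exponential precipitation decay.  All generators are pure
functions of their arguments including the seed: the same call returns
bit-identical output, and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import R_GAS
from .dissolution import ConcentrationProfile
from .errors import CapacityError, DomainError
from .flory_huggins import MeltingDepressionSeries
from .group_contribution import (GroupInventory, HansenParameters,
                                 hansen_from_inventory, load_default_group_table)
from .thermal import DSCCycle, EventKind, ThermalEvent
from .trajectory import Configuration, Particle, VolumeTemperatureSeries

__all__ = [
    "gen_melting_depression",
    "gen_hbond_configuration",
    "gen_vt_series",
    "gen_dissolution",
    "LuteolinPvpFixtures",
    "fixtures_luteolin_pvp",
    "LUTEOLIN_MOLAR_MASS",
    "LUTEOLIN_DHFUS_J_MOL",
]

#: g/mol, C15H10O6.
LUTEOLIN_MOLAR_MASS = 286.24

#: Molar fusion enthalpy of luteolin, J/mol: 187.5 J/g (DSC, first heating)
#: times the molar mass.
LUTEOLIN_DHFUS_J_MOL = 187.5 * LUTEOLIN_MOLAR_MASS


# --------------------------------------------------------------------------
# melting-point depression
# --------------------------------------------------------------------------

def gen_melting_depression(chi_true: float, m: float, dhfus: float,
                           tm_pure: float, phis: Sequence[float],
                           noise_sd_k: float = 0.0,
                           seed: int = 0) -> MeltingDepressionSeries:
    """Invert the depression relation at ``chi_true`` for each polymer fraction.

    Tm_mix solves  1/Tm_mix = 1/Tm_pure - (R/dhfus) * [ln(phi_d)
    + (1 - 1/m) phi_p + chi phi_p^2]  exactly, then optional Gaussian noise
    of standard deviation ``noise_sd_k`` (kelvin) is added.
    """
    if not phis:
        raise DomainError("phis must be non-empty")
    if noise_sd_k < 0:
        raise DomainError("noise_sd_k must be >= 0")
    rng = np.random.default_rng(seed)
    points = []
    for phi_p in phis:
        if not (0.0 < phi_p < 1.0):
            raise DomainError(f"phi_polymer {phi_p} outside (0, 1)")
        phi_d = 1.0 - phi_p
        bracket = np.log(phi_d) + (1.0 - 1.0 / m) * phi_p + chi_true * phi_p ** 2
        inv_tm = 1.0 / tm_pure - (R_GAS / dhfus) * bracket
        if inv_tm <= 0:
            raise DomainError(
                f"parameters give a non-physical Tm at phi_polymer={phi_p}"
            )
        tm = 1.0 / inv_tm + (rng.normal(0.0, noise_sd_k) if noise_sd_k > 0 else 0.0)
        if tm <= 0:
            raise DomainError("noise drove a melting point non-positive")
        points.append((float(phi_p), float(tm)))
    return MeltingDepressionSeries(tm_pure, dhfus, m, tuple(points))


# --------------------------------------------------------------------------
# hydrogen-bond configurations
# --------------------------------------------------------------------------

_SITE_SPACING = 10.0       # Angstrom between triple centres; atoms stay within
_DH_LENGTH = 1.0           # covalent donor-hydrogen bond length
_DECOY_FAR = 2.8           # H...A distance of a distance-decoy (2.5 + 0.3 margin)
_DECOY_ANGLE = 60.0        # D-H-A angle of an angle-decoy (90 - 30 margin)


def gen_hbond_configuration(n_planted: int, n_decoys: int,
                            box_edge: float = 40.0,
                            seed: int = 0) -> Configuration:
    """Periodic box with exactly ``n_planted`` compliant H-bond geometries.

    Donor-hydrogen-acceptor triples sit on a cubic grid of spacing 10
    Angstrom so no cross-triple contact can come within the 2.5 Angstrom
    criterion.  Planted triples are collinear (angle 180 deg) with
    H...acceptor drawn from [1.6, 2.3] Angstrom; decoys alternate between a
    distance violation (2.8 Angstrom, collinear) and an angle violation
    (60 deg at 2.0 Angstrom), each clearing the required 0.2 Angstrom /
    10 degree margin.  A brute-force triple enumeration re-checks the
    planted count before the configuration is returned.
    """
    if n_planted < 0 or n_decoys < 0:
        raise DomainError("counts must be non-negative")
    n_sites_axis = int(box_edge // _SITE_SPACING)
    capacity = n_sites_axis ** 3
    n_total = n_planted + n_decoys
    if n_total > capacity:
        raise CapacityError(
            f"{n_total} triples do not fit: box {box_edge} A holds {capacity} "
            f"sites at {_SITE_SPACING} A spacing"
        )
    rng = np.random.default_rng(seed)
    sites = [(i, j, k) for i in range(n_sites_axis)
             for j in range(n_sites_axis) for k in range(n_sites_axis)]
    chosen = [sites[i] for i in rng.choice(len(sites), size=n_total, replace=False)]

    particles: list[Particle] = []
    bonded: list[tuple[int, int]] = []
    next_id = 0

    def add(species: str, roles: set, pos: np.ndarray) -> int:
        nonlocal next_id
        pid = next_id
        next_id += 1
        particles.append(Particle(pid, species, frozenset(roles),
                                  tuple(np.mod(pos, box_edge))))
        return pid

    def random_unit() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    for idx, site in enumerate(chosen):
        centre = (np.array(site) + 0.5) * _SITE_SPACING
        u = random_unit()
        h_pos = centre
        d_pos = centre + u * _DH_LENGTH
        if idx < n_planted:
            d_ha = float(rng.uniform(1.6, 2.3))
            a_pos = centre - u * d_ha                      # collinear, 180 deg
        elif (idx - n_planted) % 2 == 0:
            a_pos = centre - u * _DECOY_FAR                # too far
        else:
            # acceptor at 2.0 A but with D-H-A angle 60 deg: place it 60 deg
            # away from the H->D direction (angle at H between D and A is 60)
            w = random_unit()
            w -= u * np.dot(w, u)
            w /= np.linalg.norm(w)
            a_dir = np.cos(np.radians(_DECOY_ANGLE)) * u + np.sin(
                np.radians(_DECOY_ANGLE)) * w
            a_pos = centre + a_dir * 2.0
        d_id = add("OD", {"donor_heavy"}, d_pos)
        h_id = add("H1", {"hydrogen"}, h_pos)
        add("O3", {"acceptor"}, a_pos)
        bonded.append((d_id, h_id))

    config = Configuration((box_edge,) * 3, tuple(particles), tuple(bonded))
    actual = _bruteforce_hbond_count(config)
    if actual != n_planted:
        raise CapacityError(
            f"generation self-check failed: planted {n_planted}, found {actual}"
        )
    return config


def _bruteforce_hbond_count(config: Configuration, d_max: float = 2.5,
                            angle_min: float = 90.0) -> int:
    """Independent plain-loop enumeration of compliant (D-H, A) triples."""
    box = np.array(config.box)

    def mic(d):
        return d - box * np.round(d / box)

    by_id = config.by_id()
    count = 0
    for d_id, h_id in config.bonded_pairs:
        h = np.array(by_id[h_id].position)
        d = np.array(by_id[d_id].position)
        for p in config.particles:
            if "acceptor" not in p.roles or p.id == d_id:
                continue
            ha = mic(np.array(p.position) - h)
            r = np.linalg.norm(ha)
            if r == 0 or r > d_max:
                continue
            hd = mic(d - h)
            cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * r)
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_min:
                count += 1
    return count


# --------------------------------------------------------------------------
# specific-volume cooling curves
# --------------------------------------------------------------------------

def gen_vt_series(tg_true: float = 460.0,
                  slope_rubbery: float = 6.0e-4,
                  slope_glassy: float = 2.0e-4,
                  t_range: tuple[float, float] = (203.0, 803.0),
                  n_points: int = 15,
                  v_at_tg: float = 0.85,
                  noise_rel: float = 0.0,
                  seed: int = 0) -> VolumeTemperatureSeries:
    """Two-slope specific-volume cooling curve with a kink at ``tg_true``.

    v(T) is continuous and piecewise linear: glassy expansivity below the
    kink, rubbery above, both in cm^3/g/K; ``noise_rel`` is the relative
    standard deviation of multiplicative Gaussian noise.  Points are
    returned on a descending temperature grid (a cooling run), ``n_points``
    equally spaced over ``t_range``.
    """
    if slope_rubbery == slope_glassy:
        raise DomainError("rubbery and glassy slopes must differ")
    lo, hi = t_range
    if not (lo < tg_true < hi):
        raise DomainError("tg_true must lie inside t_range")
    if noise_rel < 0:
        raise DomainError("noise_rel must be >= 0")
    rng = np.random.default_rng(seed)
    temps = np.linspace(hi, lo, n_points)          # cooling: descending
    v = np.where(temps >= tg_true,
                 v_at_tg + slope_rubbery * (temps - tg_true),
                 v_at_tg + slope_glassy * (temps - tg_true))
    if noise_rel > 0:
        v = v * (1.0 + rng.normal(0.0, noise_rel, size=v.shape))
    return VolumeTemperatureSeries(tuple(zip(map(float, temps), map(float, v))))


# --------------------------------------------------------------------------
# dissolution profiles
# --------------------------------------------------------------------------

def gen_dissolution(c_inf: float, k_rise: float, k_precip: float,
                    cs: float, times: Sequence[float],
                    noise_sd: float = 0.0, seed: int = 0,
                    sample_id: str = "synthetic") -> ConcentrationProfile:
    """First-order dissolution with optional exponential precipitation decay.

    c(t) = c_inf (1 - exp(-k_rise t)) exp(-k_precip t) + noise, truncated
    at zero.  A crystalline mimic uses ``c_inf = cs`` with ``k_precip = 0``
    (a plateau at the equilibrium solubility).
    """
    if k_rise < 0 or k_precip < 0:
        raise DomainError("rate constants must be >= 0")
    if cs <= 0:
        raise DomainError("cs must be positive")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    c = c_inf * (1.0 - np.exp(-k_rise * t)) * np.exp(-k_precip * t)
    if noise_sd > 0:
        c = c + rng.normal(0.0, noise_sd, size=c.shape)
    c = np.clip(c, 0.0, None)
    return ConcentrationProfile(sample_id, tuple(map(float, t)),
                                tuple(map(float, c)))


# --------------------------------------------------------------------------
# luteolin / PVP reference fixtures
# --------------------------------------------------------------------------

#: Molar volumes (cm^3/mol) back-solved from the published partial
#: parameters (sum(N Fdi) / delta_d), so the printed Hansen table
#: regenerates to its printed precision.  Fedors additivity alone
#: underestimates the fused tricyclic drug.
LUTEOLIN_MOLAR_VOLUME = 3450.0 / 18.08
PVP_MONOMER_MOLAR_VOLUME = 1470.0 / 16.40


@dataclass(frozen=True)
class LuteolinPvpFixtures:
    lut_inventory: GroupInventory
    pvp_inventory: GroupInventory
    lut_hansen: HansenParameters
    pvp_hansen: HansenParameters
    lut_gfa_cycle: DSCCycle
    raw_material_tgs_c: tuple[float, float]      # (PVP, luteolin)
    blend_tgs_c: tuple[float, float, float]      # 10/20/30 % w/w drug loading


def fixtures_luteolin_pvp() -> LuteolinPvpFixtures:
    """Reference inputs for the luteolin (drug) / povidone (polymer) system.

    Inventories follow the published group assignment: luteolin counts its
    four phenolic -OH, three alkene-type =CH-, one conjugated ketone -CO-,
    one ether -O-, five substituted aromatic =C< and one substituted
    benzene ring; the PVP repeat unit counts four -CH2-, one >CH-, one >N-
    and one -CO- (treated per monomer).  The DSC cycle is the drug's
    heat-cool-heat run: melt at 343.2 C (187.5 J/g), featureless cooling,
    a single glass transition at 186.5 C on reheating -- a stable glass
    former.  Blend Tgs are those of the 10/20/30 % w/w drug mixtures.
    """
    table = load_default_group_table()
    lut = GroupInventory("luteolin", (
        ("-OH", 4), ("=CH-", 3), ("-CO-", 1), ("-O-", 1), ("=C<", 5),
        ("benzene_ring_subst", 1),
    ))
    pvp = GroupInventory("PVP", (
        ("-CH2-", 4), (">CH-", 1), (">N-", 1), ("-CO-", 1),
    ), basis="per_monomer")
    cycle = DSCCycle(
        heat1=(ThermalEvent(EventKind.melting_endotherm, 343.2, 187.5),),
        cool=(),
        heat2=(ThermalEvent(EventKind.glass_transition, 186.5),),
    )
    return LuteolinPvpFixtures(
        lut_inventory=lut,
        pvp_inventory=pvp,
        lut_hansen=hansen_from_inventory(lut, table, LUTEOLIN_MOLAR_VOLUME),
        pvp_hansen=hansen_from_inventory(pvp, table, PVP_MONOMER_MOLAR_VOLUME),
        lut_gfa_cycle=cycle,
        raw_material_tgs_c=(172.3, 186.5),
        blend_tgs_c=(181.0, 179.7, 177.9),
    )
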