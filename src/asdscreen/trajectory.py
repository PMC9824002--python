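"""Post-processing of amorphous-assembly configurations.

Provides the radial distribution function g(r) between two atom
selections under orthorhombic periodic boundaries, geometric
hydrogen-bond detection (H...acceptor distance and donor-H...acceptor
angle criteria), interaction-strength banding of contact distances, and
glass-transition estimation from the kink of a specific-volume-versus-
temperature cooling curve.

The RDF of selections A and B is the frame-averaged histogram of
minimum-image pair distances, normalized so an ideal gas gives g = 1:

    g(r) = <n_AB(r)> * V / [(N_A N_B - N_AB) * 4 pi r^2 dr]

where n_AB(r) counts ordered cross pairs (i in A, j in B, i != j) in the
shell [r, r + dr), V is the box volume, and N_AB is the number of atoms
in both selections, so that A = B reduces to the textbook same-species
normalization N(N-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import (DegenerateFitError, DomainError, InsufficientDataError,
                     SelectionError, StructuralError)

__all__ = [
    "Particle",
    "Configuration",
    "RDFProfile",
    "HBondRecord",
    "VolumeTemperatureSeries",
    "TgEstimate",
    "radial_distribution",
    "find_hbonds",
    "classify_contact_strength",
    "estimate_tg_from_volume",
]

Role = Literal["donor_heavy", "hydrogen", "acceptor"]


@dataclass(frozen=True)
class Particle:
    id: int
    species: str
    roles: frozenset        # subset of {"donor_heavy", "hydrogen", "acceptor"}
    position: tuple[float, float, float]   # Angstrom


@dataclass(frozen=True)
class Configuration:
    """Labelled particles in an orthorhombic periodic box (Angstrom).

    ``bonded_pairs`` lists covalent (donor_heavy_id, hydrogen_id)
    attachments; every hydrogen taking part in H-bond detection must appear
    in exactly one such pair.
    """

    box: tuple[float, float, float]
    particles: tuple[Particle, ...]
    bonded_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if min(self.box) <= 0:
            raise DomainError("box edges must be positive")
        ids = [p.id for p in self.particles]
        if len(set(ids)) != len(ids):
            raise DomainError("particle ids must be unique")
        for p in self.particles:
            if not all(np.isfinite(p.position)):
                raise DomainError(f"particle {p.id}: non-finite position")
        h_counts: dict[int, int] = {}
        for _, h in self.bonded_pairs:
            h_counts[h] = h_counts.get(h, 0) + 1
        if any(c > 1 for c in h_counts.values()):
            raise StructuralError("a hydrogen is bonded to more than one donor")

    def by_id(self) -> dict[int, Particle]:
        return {p.id: p for p in self.particles}

    def positions(self, particles: Sequence[Particle] | None = None) -> np.ndarray:
        ps = self.particles if particles is None else particles
        return np.array([p.position for p in ps], dtype=float)


@dataclass(frozen=True)
class RDFProfile:
    r_centers: np.ndarray        # bin centers (i + 1/2) dr, Angstrom
    g_values: np.ndarray         # dimensionless
    dr: float
    n_a: float                   # frame-averaged selection sizes
    n_b: float
    n_ab: float                  # frame-averaged overlap count

    def mean_over(self, r_lo: float, r_hi: float) -> float:
        mask = (self.r_centers >= r_lo) & (self.r_centers <= r_hi)
        return float(self.g_values[mask].mean())


@dataclass(frozen=True)
class HBondRecord:
    donor_id: int
    hydrogen_id: int
    acceptor_id: int
    h_acceptor_distance: float   # Angstrom, minimum image
    dha_angle: float             # degrees, vertex at the hydrogen


@dataclass(frozen=True)
class VolumeTemperatureSeries:
    """Specific volume v (cm^3/g) versus temperature (K), recorded on cooling."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 6:
            raise InsufficientDataError("v-T series needs at least 6 points")
        temps = [t for t, _ in self.points]
        diffs = np.diff(temps)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise DomainError("temperatures must be strictly monotone")


@dataclass(frozen=True)
class TgEstimate:
    tg: float                            # K, intersection of the two lines
    rubbery_line: tuple[float, float]    # (slope, intercept), high-T side
    glassy_line: tuple[float, float]     # (slope, intercept), low-T side
    split_index: int                     # points [0, split) are glassy (ascending order)
    sse: float
    degenerate: bool = False             # near-parallel lines or Tg outside data


# --------------------------------------------------------------------------
# periodic geometry helpers
# --------------------------------------------------------------------------

def minimum_image(dvec: np.ndarray, box: Sequence[float]) -> np.ndarray:
    """Wrap displacement vectors (last axis = xyz) into the central image."""
    b = np.asarray(box, dtype=float)
    return dvec - b * np.round(dvec / b)


def _pair_distances(pos_a: np.ndarray, pos_b: np.ndarray,
                    box: Sequence[float]) -> np.ndarray:
    d = pos_a[:, None, :] - pos_b[None, :, :]
    return np.linalg.norm(minimum_image(d, box), axis=-1)


# --------------------------------------------------------------------------
# radial distribution function
# --------------------------------------------------------------------------

def radial_distribution(frames: Sequence[Configuration],
                        sel_a: Callable[[Particle], bool],
                        sel_b: Callable[[Particle], bool],
                        dr: float = 0.05,
                        r_max: float | None = None) -> RDFProfile:
    """Frame-averaged g(r) between two particle selections.

    ``r_max`` defaults to half the shortest box edge of the first frame and
    may not exceed half the shortest edge of any frame (minimum-image
    validity).  Self pairs of the overlap A-and-B are excluded both from
    the histogram (i != j) and from the normalization (N_A N_B - N_AB).
    """
    if not frames:
        raise DomainError("no frames supplied")
    if dr <= 0:
        raise DomainError("dr must be positive")
    half_min_edge = min(min(f.box) for f in frames) / 2.0
    if r_max is None:
        r_max = half_min_edge
    if r_max > half_min_edge + 1e-12:
        raise DomainError(
            f"r_max={r_max} exceeds half the smallest box edge ({half_min_edge})"
        )
    n_bins = int(np.ceil(r_max / dr - 1e-12))
    edges = np.arange(n_bins + 1) * dr
    counts = np.zeros(n_bins)
    na_sum = nb_sum = nab_sum = 0.0
    inv_pair_density_sum = 0.0
    for frame in frames:
        a = [p for p in frame.particles if sel_a(p)]
        b = [p for p in frame.particles if sel_b(p)]
        if not a or not b:
            raise SelectionError("a selection matched no particles in a frame")
        ids_a = {p.id for p in a}
        n_ab = sum(1 for p in b if p.id in ids_a)
        n_pairs = len(a) * len(b) - n_ab
        if n_pairs <= 0:
            raise SelectionError("selections leave no cross pairs")
        dists = _pair_distances(frame.positions(a), frame.positions(b), frame.box)
        # mask self pairs (same particle id in both selections)
        ids_b_arr = np.array([p.id for p in b])
        ids_a_arr = np.array([p.id for p in a])
        self_mask = ids_a_arr[:, None] == ids_b_arr[None, :]
        flat = dists[~self_mask]
        hist, _ = np.histogram(flat[flat < r_max], bins=edges)
        counts += hist
        v = float(np.prod(frame.box))
        na_sum += len(a)
        nb_sum += len(b)
        nab_sum += n_ab
        inv_pair_density_sum += v / n_pairs
    n_frames = len(frames)
    r_centers = (np.arange(n_bins) + 0.5) * dr
    shell = 4.0 * np.pi * r_centers ** 2 * dr
    # <count per frame> / (shell volume * pair density), pair density averaged
    g = (counts / n_frames) * (inv_pair_density_sum / n_frames) / shell
    return RDFProfile(r_centers, g, dr,
                      na_sum / n_frames, nb_sum / n_frames, nab_sum / n_frames)


def radial_distribution_bruteforce(frames: Sequence[Configuration],
                                   sel_a: Callable[[Particle], bool],
                                   sel_b: Callable[[Particle], bool],
                                   dr: float = 0.05,
                                   r_max: float | None = None) -> RDFProfile:
    """Plain double-loop reference implementation (oracle for small systems)."""
    if not frames:
        raise DomainError("no frames supplied")
    half_min_edge = min(min(f.box) for f in frames) / 2.0
    if r_max is None:
        r_max = half_min_edge
    n_bins = int(np.ceil(r_max / dr - 1e-12))
    counts = np.zeros(n_bins)
    na = nb = nab = 0.0
    inv_pd = 0.0
    for frame in frames:
        a = [p for p in frame.particles if sel_a(p)]
        b = [p for p in frame.particles if sel_b(p)]
        if not a or not b:
            raise SelectionError("empty selection")
        ids_a = {p.id for p in a}
        n_ab = sum(1 for p in b if p.id in ids_a)
        for pa in a:
            for pb in b:
                if pa.id == pb.id:
                    continue
                d = np.array(pa.position) - np.array(pb.position)
                r = float(np.linalg.norm(minimum_image(d, frame.box)))
                if r < r_max:
                    counts[int(r / dr)] += 1
        na += len(a)
        nb += len(b)
        nab += n_ab
        inv_pd += float(np.prod(frame.box)) / (len(a) * len(b) - n_ab)
    nf = len(frames)
    r_centers = (np.arange(n_bins) + 0.5) * dr
    shell = 4.0 * np.pi * r_centers ** 2 * dr
    g = (counts / nf) * (inv_pd / nf) / shell
    return RDFProfile(r_centers, g, dr, na / nf, nb / nf, nab / nf)


# --------------------------------------------------------------------------
# hydrogen bonds
# --------------------------------------------------------------------------

def find_hbonds(frame: Configuration, d_max: float = 2.5,
                angle_min: float = 90.0) -> list[HBondRecord]:
    """Geometric H-bond detection.

    A record is emitted for every covalent donor-hydrogen pair and acceptor
    with minimum-image H...acceptor distance <= ``d_max`` (Angstrom) and
    donor-hydrogen-acceptor angle (vertex at the hydrogen) >= ``angle_min``
    (degrees).  An acceptor that is the hydrogen's own donor is skipped.
    """
    if d_max <= 0:
        raise DomainError("d_max must be positive")
    by_id = frame.by_id()
    hydrogens = [p for p in frame.particles if "hydrogen" in p.roles]
    donor_of = {h: d for d, h in frame.bonded_pairs}
    for h in hydrogens:
        if h.id not in donor_of:
            raise StructuralError(f"hydrogen {h.id} has no bonded donor")
    acceptors = [p for p in frame.particles if "acceptor" in p.roles]
    records: list[HBondRecord] = []
    if not acceptors:
        return records
    acc_pos = frame.positions(acceptors)
    for h in hydrogens:
        d_part = by_id[donor_of[h.id]]
        h_pos = np.array(h.position)
        # H -> A displacements (minimum image)
        ha = minimum_image(acc_pos - h_pos, frame.box)
        dist = np.linalg.norm(ha, axis=1)
        hd = minimum_image(np.array(d_part.position) - h_pos, frame.box)
        hd_norm = np.linalg.norm(hd)
        if hd_norm == 0:
            raise StructuralError(f"donor {d_part.id} coincides with hydrogen {h.id}")
        for k, acc in enumerate(acceptors):
            if acc.id == d_part.id or dist[k] > d_max or dist[k] == 0:
                continue
            cosang = float(np.dot(hd, ha[k]) / (hd_norm * dist[k]))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle >= angle_min:
                records.append(HBondRecord(d_part.id, h.id, acc.id,
                                           float(dist[k]), angle))
    return records


ContactBand = Literal["strong", "moderate", "weak", "none"]


def classify_contact_strength(distance: float,
                              distance_kind: Literal["donor_acceptor",
                                                     "hydrogen_acceptor"]
                              ) -> tuple[ContactBand, str]:
    """Band a contact distance by interaction strength.

    The bands are stated for donor-acceptor separations: <= 2.5 Angstrom
    strong (the 2.2-2.5 range and anything shorter), 2.5-3.2 moderate
    (predominantly electrostatic), 3.2-4.0 weak electrostatic, beyond 4.0
    none.  Hydrogen-acceptor distances are banded with the same cutoffs but
    the returned kind tags them explicitly so the two geometries are never
    silently conflated.
    """
    if distance <= 0:
        raise DomainError("distance must be positive")
    if distance_kind not in ("donor_acceptor", "hydrogen_acceptor"):
        raise DomainError(f"unknown distance kind {distance_kind!r}")
    if distance <= 2.5:
        band: ContactBand = "strong"
    elif distance <= 3.2:
        band = "moderate"
    elif distance <= 4.0:
        band = "weak"
    else:
        band = "none"
    return band, distance_kind


# --------------------------------------------------------------------------
# Tg from specific volume
# --------------------------------------------------------------------------

def estimate_tg_from_volume(series: VolumeTemperatureSeries,
                            min_points_per_side: int = 3,
                            parallel_tol: float = 1e-12) -> TgEstimate:
    """Bilinear (broken-stick) fit of v(T); Tg is the line intersection.

    Points are sorted by ascending temperature; for every admissible split
    an OLS line is fitted to each side and the split with the smallest
    total squared residual wins.  The result is flagged degenerate when the
    two slopes differ by less than ``parallel_tol`` (cm^3/g/K) or the
    intersection falls outside the observed temperature range.
    """
    pts = sorted(series.points)
    t = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    n = len(t)
    if n < 2 * min_points_per_side:
        raise InsufficientDataError(
            f"need at least {2 * min_points_per_side} points for a bilinear fit"
        )
    best = None
    for split in range(min_points_per_side, n - min_points_per_side + 1):
        lo = stats.linregress(t[:split], v[:split])
        hi = stats.linregress(t[split:], v[split:])
        sse = (np.sum((v[:split] - (lo.slope * t[:split] + lo.intercept)) ** 2)
               + np.sum((v[split:] - (hi.slope * t[split:] + hi.intercept)) ** 2))
        if best is None or sse < best[0]:
            best = (float(sse), split, lo, hi)
    assert best is not None
    sse, split, lo, hi = best
    dslope = hi.slope - lo.slope
    if abs(dslope) < parallel_tol:
        tg = float(t[split - 1] + t[split]) / 2.0   # nominal; flagged degenerate
        return TgEstimate(tg, (float(hi.slope), float(hi.intercept)),
                          (float(lo.slope), float(lo.intercept)), split, sse,
                          degenerate=True)
    tg = float((lo.intercept - hi.intercept) / dslope)
    degenerate = not (t[0] <= tg <= t[-1])
    return TgEstimate(tg, (float(hi.slope), float(hi.intercept)),
                      (float(lo.slope), float(lo.intercept)), split, sse,
                      degenerate=degenerate)
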