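"""RDF, hydrogen-bond detection, strength banding, and Tg from v(T)."""

import numpy as np
import pytest

from asdscreen.errors import (DomainError, InsufficientDataError,
                              SelectionError, StructuralError)
from asdscreen.synthetic import gen_hbond_configuration, gen_vt_series
from asdscreen.trajectory import (
    Configuration, Particle, VolumeTemperatureSeries, classify_contact_strength,
    estimate_tg_from_volume, find_hbonds, radial_distribution,
)

from conftest import bruteforce_hbond_triples, bruteforce_rdf, make_random_config

ALL = lambda p: True  # noqa: E731


# --------------------------------------------------------------------------
# radial distribution function
# --------------------------------------------------------------------------

def test_rdf_matches_bruteforce_oracle_bin_by_bin():
    frames = [make_random_config(40, 12.0, seed=s) for s in (0, 1, 2)]
    prof = radial_distribution(frames, ALL, ALL, dr=0.25, r_max=6.0)
    oracle = bruteforce_rdf(frames, ALL, ALL, dr=0.25, r_max=6.0)
    np.testing.assert_allclose(prof.g_values, oracle, rtol=1e-12, atol=1e-12)


def test_rdf_two_particles_single_bin_at_separation():
    box = 60.0
    particles = (Particle(0, "H1", frozenset(), (10.0, 10.0, 10.0)),
                 Particle(1, "O1", frozenset(), (10.0, 10.0, 11.92)))
    frame = Configuration((box, box, box), particles)
    prof = radial_distribution([frame], ALL, ALL, dr=0.05, r_max=10.0)
    nonzero = np.nonzero(prof.g_values)[0]
    assert len(nonzero) == 1
    lo = prof.r_centers[nonzero[0]] - prof.dr / 2
    assert lo <= 1.92 < lo + prof.dr


def test_rdf_counting_conservation():
    # sum over bins of g * pair_density * shell volume = mean pair count
    frames = [make_random_config(30, 10.0, seed=9)]
    prof = radial_distribution(frames, ALL, ALL, dr=0.2, r_max=5.0)
    n = 30
    pair_density = (n * n - n) / 10.0 ** 3
    shell = 4 * np.pi * prof.r_centers ** 2 * prof.dr
    recovered = float((prof.g_values * pair_density * shell).sum())
    dists = bruteforce_rdf(frames, ALL, ALL, dr=5.0, r_max=5.0)  # single bin count
    expected = float(dists[0] * pair_density * 4 * np.pi * 2.5 ** 2 * 5.0)
    assert recovered == pytest.approx(expected, rel=1e-9)


def test_rdf_distinct_selections_exclude_overlap_correctly():
    rng_frames = [make_random_config(20, 10.0, seed=4)]
    sel_even = lambda p: p.id % 2 == 0  # noqa: E731
    prof = radial_distribution(rng_frames, sel_even, ALL, dr=0.5, r_max=5.0)
    oracle = bruteforce_rdf(rng_frames, sel_even, ALL, dr=0.5, r_max=5.0)
    np.testing.assert_allclose(prof.g_values, oracle, rtol=1e-12)
    assert prof.n_ab == 10


def test_rdf_rejects_rmax_beyond_half_box():
    frames = [make_random_config(10, 10.0, seed=0)]
    with pytest.raises(DomainError):
        radial_distribution(frames, ALL, ALL, dr=0.1, r_max=5.1)


def test_rdf_rejects_empty_selection():
    frames = [make_random_config(10, 10.0, seed=0)]
    with pytest.raises(SelectionError):
        radial_distribution(frames, lambda p: p.species == "Zz", ALL, dr=0.1)


# --------------------------------------------------------------------------
# hydrogen bonds
# --------------------------------------------------------------------------

def _triple(h_a_dist, angle_deg, box=50.0):
    """One donor-hydrogen-acceptor triple with the given H..A geometry."""
    h = np.array([25.0, 25.0, 25.0])
    d = h + np.array([0.0, 0.0, 1.0])
    theta = np.radians(angle_deg)
    a = h + h_a_dist * np.array([np.sin(theta), 0.0, np.cos(theta)])
    particles = (Particle(0, "OD", frozenset({"donor_heavy"}), tuple(d)),
                 Particle(1, "H1", frozenset({"hydrogen"}), tuple(h)),
                 Particle(2, "O3", frozenset({"acceptor"}), tuple(a)))
    return Configuration((box, box, box), particles, ((0, 1),))


def test_collinear_contact_inside_both_criteria_detected():
    records = find_hbonds(_triple(1.8, 180.0))
    assert len(records) == 1
    rec = records[0]
    assert rec.h_acceptor_distance == pytest.approx(1.8)
    assert rec.dha_angle == pytest.approx(180.0)


@pytest.mark.parametrize("dist, angle, n", [
    (2.6, 180.0, 0),      # distance beyond the 2.5 A maximum
    (2.0, 60.0, 0),       # angle below the 90 degree minimum
    (2.5, 90.0, 1),       # both criteria inclusive at the boundary
])
def test_criteria_boundaries(dist, angle, n):
    assert len(find_hbonds(_triple(dist, angle))) == n


def test_acceptor_never_its_own_donor():
    # donor also labelled acceptor: the bonded D may not accept from its own H
    h = (25.0, 25.0, 25.0)
    d = (25.0, 25.0, 26.0)
    particles = (Particle(0, "OD", frozenset({"donor_heavy", "acceptor"}), d),
                 Particle(1, "H1", frozenset({"hydrogen"}), h))
    frame = Configuration((50.0,) * 3, particles, ((0, 1),))
    assert find_hbonds(frame) == []


def test_hydrogen_without_donor_is_structural_error():
    particles = (Particle(0, "H1", frozenset({"hydrogen"}), (1.0, 1.0, 1.0)),
                 Particle(1, "O3", frozenset({"acceptor"}), (1.0, 1.0, 2.5)))
    frame = Configuration((50.0,) * 3, particles)
    with pytest.raises(StructuralError):
        find_hbonds(frame)


def test_detection_across_periodic_boundary():
    # H at the box face, acceptor just across it: minimum image sees 1.6 A
    box = 20.0
    particles = (Particle(0, "OD", frozenset({"donor_heavy"}), (1.3, 5.0, 5.0)),
                 Particle(1, "H1", frozenset({"hydrogen"}), (0.3, 5.0, 5.0)),
                 Particle(2, "O3", frozenset({"acceptor"}), (18.7, 5.0, 5.0)))
    frame = Configuration((box, box, box), particles, ((0, 1),))
    records = find_hbonds(frame)
    assert len(records) == 1
    assert records[0].h_acceptor_distance == pytest.approx(1.6)


@pytest.mark.parametrize("k, j", [(0, 10), (5, 5), (12, 8)])
def test_planted_configurations_match_bruteforce(k, j):
    config = gen_hbond_configuration(k, j, box_edge=50.0, seed=11)
    records = find_hbonds(config)
    assert len(records) == k
    oracle = bruteforce_hbond_triples(config)
    assert sorted((r.donor_id, r.hydrogen_id, r.acceptor_id) for r in records) \
        == sorted(oracle)


def test_hbonds_invariant_to_reindexing_and_rigid_translation():
    config = gen_hbond_configuration(6, 4, box_edge=40.0, seed=2)
    base = {(r.donor_id, r.hydrogen_id, r.acceptor_id)
            for r in find_hbonds(config)}

    # rigid translation with periodic wrapping
    shift = np.array([13.7, -4.2, 25.1])
    moved = Configuration(config.box, tuple(
        Particle(p.id, p.species, p.roles,
                 tuple(np.mod(np.array(p.position) + shift, config.box)))
        for p in config.particles), config.bonded_pairs)
    assert {(r.donor_id, r.hydrogen_id, r.acceptor_id)
            for r in find_hbonds(moved)} == base

    # relabel ids by an affine map
    remap = {p.id: 1000 - p.id for p in config.particles}
    relabeled = Configuration(config.box, tuple(
        Particle(remap[p.id], p.species, p.roles, p.position)
        for p in config.particles),
        tuple((remap[d], remap[h]) for d, h in config.bonded_pairs))
    assert {(r.donor_id, r.hydrogen_id, r.acceptor_id)
            for r in find_hbonds(relabeled)} == {
        (remap[d], remap[h], remap[a]) for d, h, a in base}


# --------------------------------------------------------------------------
# strength bands
# --------------------------------------------------------------------------

@pytest.mark.parametrize("dist, band", [
    (2.3, "strong"), (2.0, "strong"), (2.8, "moderate"), (3.5, "weak"),
    (4.5, "none"),
])
def test_contact_strength_bands(dist, band):
    got_band, kind = classify_contact_strength(dist, "donor_acceptor")
    assert got_band == band
    assert kind == "donor_acceptor"


def test_contact_strength_tags_hydrogen_acceptor_kind():
    band, kind = classify_contact_strength(1.92, "hydrogen_acceptor")
    assert kind == "hydrogen_acceptor"
    assert band == "strong"


def test_contact_strength_rejects_nonpositive_distance():
    with pytest.raises(DomainError):
        classify_contact_strength(0.0, "donor_acceptor")


# --------------------------------------------------------------------------
# Tg from specific volume
# --------------------------------------------------------------------------

def test_noiseless_bilinear_kink_recovered():
    series = gen_vt_series(tg_true=460.0, noise_rel=0.0)
    est = estimate_tg_from_volume(series)
    assert not est.degenerate
    assert est.tg == pytest.approx(460.0, abs=0.1)
    assert est.rubbery_line[0] == pytest.approx(6.0e-4, rel=1e-6)
    assert est.glassy_line[0] == pytest.approx(2.0e-4, rel=1e-6)


def test_estimate_invariant_to_scan_direction():
    series = gen_vt_series(noise_rel=0.01, seed=5)
    reversed_series = VolumeTemperatureSeries(series.points[::-1])
    a = estimate_tg_from_volume(series)
    b = estimate_tg_from_volume(reversed_series)
    assert a.tg == pytest.approx(b.tg, rel=1e-12)


def test_single_straight_line_flagged_degenerate():
    temps = np.linspace(800.0, 200.0, 12)
    series = VolumeTemperatureSeries(tuple(zip(temps, 0.5 + 3e-4 * temps)))
    assert estimate_tg_from_volume(series).degenerate


def test_vt_series_invariants():
    with pytest.raises(InsufficientDataError):
        VolumeTemperatureSeries(((500.0, 0.9), (400.0, 0.8)))
    temps = [500.0, 450.0, 470.0, 400.0, 350.0, 300.0]
    with pytest.raises(DomainError):
        VolumeTemperatureSeries(tuple(zip(temps, [0.9] * 6)))
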