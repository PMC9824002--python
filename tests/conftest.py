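import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from asdscreen.group_contribution import load_default_group_table
from asdscreen.synthetic import fixtures_luteolin_pvp
from asdscreen.trajectory import Configuration, Particle


@pytest.fixture(scope="session")
def group_table():
    return load_default_group_table()


@pytest.fixture(scope="session")
def lut_pvp():
    return fixtures_luteolin_pvp()


def make_random_config(n: int, box: float, seed: int,
                       species: str = "X") -> Configuration:
    """Uniformly random particles in a cubic periodic box (no roles)."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box, size=(n, 3))
    particles = tuple(
        Particle(i, species, frozenset(), tuple(p)) for i, p in enumerate(pos)
    )
    return Configuration((box, box, box), particles)


def bruteforce_rdf(frames, sel_a, sel_b, dr, r_max):
    """Independent triple-loop RDF oracle with its own minimum-image code."""
    n_bins = int(np.ceil(r_max / dr - 1e-12))
    counts = np.zeros(n_bins)
    inv_pd = 0.0
    for frame in frames:
        box = np.array(frame.box)
        a = [p for p in frame.particles if sel_a(p)]
        b = [p for p in frame.particles if sel_b(p)]
        ids_a = {p.id for p in a}
        n_ab = sum(1 for p in b if p.id in ids_a)
        for pa in a:
            for pb in b:
                if pa.id == pb.id:
                    continue
                d = np.array(pa.position) - np.array(pb.position)
                d -= box * np.round(d / box)
                r = np.sqrt((d ** 2).sum())
                if r < r_max:
                    counts[int(r / dr)] += 1
        inv_pd += box.prod() / (len(a) * len(b) - n_ab)
    nf = len(frames)
    r_centers = (np.arange(n_bins) + 0.5) * dr
    return counts / nf * (inv_pd / nf) / (4 * np.pi * r_centers ** 2 * dr)


def bruteforce_hbond_triples(config: Configuration, d_max=2.5, angle_min=90.0):
    """Independent enumeration of compliant (donor, hydrogen, acceptor) triples."""
    box = np.array(config.box)

    def mic(d):
        return d - box * np.round(d / box)

    by_id = {p.id: p for p in config.particles}
    triples = []
    for d_id, h_id in config.bonded_pairs:
        h = np.array(by_id[h_id].position)
        d = np.array(by_id[d_id].position)
        for p in config.particles:
            if "acceptor" not in p.roles or p.id == d_id:
                continue
            ha = mic(np.array(p.position) - h)
            r = np.sqrt((ha ** 2).sum())
            if r == 0 or r > d_max:
                continue
            hd = mic(d - h)
            cosang = np.dot(hd, ha) / (np.sqrt((hd ** 2).sum()) * r)
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_min:
                triples.append((d_id, h_id, p.id))
    return triples
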