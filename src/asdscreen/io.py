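"""File formats: CSV series, JSON event lists, and a plain-text extended-XYZ
dialect for role-labelled periodic configurations.

Conventions: CSV is comma-separated, dot-decimal, UTF-8, with a mandatory
header row.  Temperature columns are named explicitly (``temp_c`` or
``temp_k``); the unit is never inferred.  The XYZ dialect stores one frame
per block: an atom count line, a comment line holding a JSON object with
``box`` (three edge lengths, Angstrom) and ``bonded_pairs`` (covalent
donor-hydrogen id pairs), then one line per atom::

    species  x  y  z  id  roles

where ``roles`` is a comma-joined subset of donor_heavy/hydrogen/acceptor
or ``-`` for none.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .dissolution import ConcentrationProfile
from .errors import ParseError
from .thermal import DSCCycle, EventKind, TGATrace, ThermalEvent
from .trajectory import Configuration, Particle, VolumeTemperatureSeries

__all__ = [
    "read_xyz_frames",
    "write_xyz_frames",
    "read_dsc_cycle",
    "write_dsc_cycle",
    "read_tga_trace",
    "read_vt_series",
    "write_vt_series",
    "read_concentration_profiles",
    "write_concentration_profiles",
    "parse_selection",
    "load_dataset",
]

_ROLES = {"donor_heavy", "hydrogen", "acceptor"}


# --------------------------------------------------------------------------
# extended XYZ
# --------------------------------------------------------------------------

def read_xyz_frames(path) -> list[Configuration]:
    lines = Path(path).read_text().splitlines()
    frames: list[Configuration] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected an atom count") from None
        try:
            meta = json.loads(lines[i + 1])
            box = tuple(float(x) for x in meta["box"])
            bonded = tuple((int(d), int(h)) for d, h in meta.get("bonded_pairs", []))
        except (KeyError, ValueError, json.JSONDecodeError, IndexError):
            raise ParseError(f"line {i + 2}: malformed frame header JSON") from None
        particles = []
        for k in range(n_atoms):
            ln = i + 2 + k
            try:
                parts = lines[ln].split()
                species, x, y, z, pid, roles_s = (parts[0], *parts[1:5], parts[5])
            except (IndexError, ValueError):
                raise ParseError(f"line {ln + 1}: malformed atom record") from None
            roles = frozenset() if roles_s == "-" else frozenset(roles_s.split(","))
            if not roles <= _ROLES:
                raise ParseError(f"line {ln + 1}: unknown role in {roles_s!r}")
            particles.append(Particle(int(pid), species,
                                      roles, (float(x), float(y), float(z))))
        frames.append(Configuration(box, tuple(particles), bonded))
        i += 2 + n_atoms
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames


def write_xyz_frames(path, frames: Sequence[Configuration]) -> None:
    out = []
    for frame in frames:
        out.append(str(len(frame.particles)))
        out.append(json.dumps({"box": list(frame.box),
                               "bonded_pairs": [list(bp) for bp in frame.bonded_pairs]}))
        for p in frame.particles:
            roles = ",".join(sorted(p.roles)) if p.roles else "-"
            x, y, z = p.position
            out.append(f"{p.species} {x:.17g} {y:.17g} {z:.17g} {p.id} {roles}")
    Path(path).write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# DSC events (JSON)
# --------------------------------------------------------------------------

def read_dsc_cycle(path) -> DSCCycle:
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: invalid JSON ({e})") from None
    segments = {}
    for seg in ("heat1", "cool", "heat2"):
        events = []
        for j, ev in enumerate(raw.get(seg, [])):
            try:
                events.append(ThermalEvent(EventKind(ev["kind"]),
                                           float(ev["temp_c"]),
                                           float(ev.get("enthalpy_j_g", 0.0))))
            except (KeyError, ValueError) as e:
                raise ParseError(f"{path}: {seg}[{j}]: {e}") from None
        segments[seg] = tuple(events)
    return DSCCycle(**segments)


def write_dsc_cycle(path, cycle: DSCCycle) -> None:
    doc = {seg: [{"kind": e.kind.value, "temp_c": e.temperature_c,
                  "enthalpy_j_g": e.enthalpy_j_g}
                 for e in getattr(cycle, seg)]
           for seg in ("heat1", "cool", "heat2")}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# --------------------------------------------------------------------------
# tabular CSV series
# --------------------------------------------------------------------------

def _read_csv(path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_tga_trace(path) -> TGATrace:
    df = _read_csv(path, {"temp_c", "weight_pct"})
    return TGATrace(tuple(zip(df["temp_c"].astype(float),
                              df["weight_pct"].astype(float))))


def read_vt_series(path) -> VolumeTemperatureSeries:
    df = _read_csv(path, {"temp_k", "v_cm3_g"})
    return VolumeTemperatureSeries(tuple(zip(df["temp_k"].astype(float),
                                             df["v_cm3_g"].astype(float))))


def write_vt_series(path, series: VolumeTemperatureSeries) -> None:
    pd.DataFrame(series.points, columns=["temp_k", "v_cm3_g"]).to_csv(path, index=False)


def read_concentration_profiles(path) -> dict[str, ConcentrationProfile]:
    """Long-format CSV: time_min, conc_ug_ml, sample_id (sample_id optional
    for a single profile, defaulting to the file stem)."""
    df = pd.read_csv(path)
    if not {"time_min", "conc_ug_ml"} <= set(df.columns):
        raise ParseError(f"{path}: need columns time_min, conc_ug_ml")
    if "sample_id" not in df.columns:
        df = df.assign(sample_id=Path(path).stem)
    profiles = {}
    for sid, grp in df.groupby("sample_id", sort=True):
        times = grp["time_min"].astype(float).tolist()
        for row, (a, b) in enumerate(zip(times, times[1:])):
            if b <= a:
                raise ParseError(
                    f"{path}: sample {sid!r} row {row + 1}: non-increasing time {b}"
                )
        profiles[str(sid)] = ConcentrationProfile(
            str(sid), tuple(times), tuple(grp["conc_ug_ml"].astype(float)))
    return profiles


def write_concentration_profiles(path, profiles: Iterable[ConcentrationProfile]) -> None:
    rows = [(p.sample_id, t, c)
            for p in profiles for t, c in zip(p.times, p.concentrations)]
    pd.DataFrame(rows, columns=["sample_id", "time_min", "conc_ug_ml"]).to_csv(
        path, index=False)


# --------------------------------------------------------------------------
# selections and generic loading
# --------------------------------------------------------------------------

def parse_selection(text: str) -> Callable[[Particle], bool]:
    """Parse ``"species:H1"``, ``"role:hydrogen"`` or ``&``-joined terms."""
    clauses = []
    for term in text.split("&"):
        term = term.strip()
        if term.startswith("species:"):
            value = term.split(":", 1)[1]
            clauses.append(("species", value))
        elif term.startswith("role:"):
            value = term.split(":", 1)[1]
            if value not in _ROLES:
                raise ParseError(f"unknown role {value!r} in selection {text!r}")
            clauses.append(("role", value))
        elif term == "all":
            clauses.append(("all", ""))
        else:
            raise ParseError(f"cannot parse selection term {term!r}")

    def predicate(p: Particle) -> bool:
        for kind, value in clauses:
            if kind == "species" and p.species != value:
                return False
            if kind == "role" and value not in p.roles:
                return False
        return True

    return predicate


_FORMATS = {"csv_tabular", "json_events", "xyz_frames"}

_EXT_TO_FORMAT = {".csv": "csv_tabular", ".json": "json_events",
                  ".xyz": "xyz_frames"}


def load_dataset(path, format: str | None = None):
    """Load a file into its typed domain object.

    ``csv_tabular`` dispatches on the header: TGA traces (temp_c,
    weight_pct), specific-volume series (temp_k, v_cm3_g), concentration
    profiles (time_min, conc_ug_ml) or melting-depression points
    (phi_polymer plus tm_k or tm_c; returned as a DataFrame because the
    pure-drug constants live in a sidecar, see flory_huggins).
    """
    path = Path(path)
    if format is None:
        format = _EXT_TO_FORMAT.get(path.suffix.lower())
        if format is None:
            raise ParseError(f"{path}: cannot infer format from extension")
    if format not in _FORMATS:
        raise ParseError(f"unknown format {format!r}")
    if format == "xyz_frames":
        return read_xyz_frames(path)
    if format == "json_events":
        return read_dsc_cycle(path)
    header = set(pd.read_csv(path, nrows=0).columns)
    if {"temp_c", "weight_pct"} <= header:
        return read_tga_trace(path)
    if {"temp_k", "v_cm3_g"} <= header:
        return read_vt_series(path)
    if {"time_min", "conc_ug_ml"} <= header:
        return read_concentration_profiles(path)
    if "phi_polymer" in header and ({"tm_k"} & header or {"tm_c"} & header):
        return pd.read_csv(path)
    raise ParseError(f"{path}: unrecognized CSV schema (columns {sorted(header)})")
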