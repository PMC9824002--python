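"""Pipeline driver: run the screening stages from one declarative config
and emit a machine-readable report.

A run config (YAML or dict) selects stages and their parameters::

    seed: 1
    stages:
      hsp:  {source: fixture}
      gfa:  {source: fixture}
      chi:  {generate: {chi_true: -0.844, m: 1000, phis: [0.05, 0.1, 0.2]}}
      tgfit: {generate: {tg_true: 460.0}}
      hbonds: {generate: {n_planted: 5, n_decoys: 5}}
      dissolution: {generate: {fold: 6.0}, cs: 5.7}

Each stage either reads an input file (``path``), uses the bundled
luteolin/PVP fixtures (``source: fixture``) or generates synthetic input
(``generate: {...}``).  Stages run in a fixed dependency-free order; a
stage failure is recorded in the report and later stages still run.
Identical config and inputs give an identical report payload (timestamps
excluded from the comparison and the config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .dissolution import compare_inhibitors, profile_metrics
from .errors import AsdScreenError, ParseError
from .flory_huggins import MeltingDepressionSeries, fit_chi, mixing_free_energy_curve
from .group_contribution import (classify_miscibility_delta, hansen_from_inventory,
                                 load_default_group_table)
from .io import (parse_selection, read_concentration_profiles, read_dsc_cycle,
                 read_tga_trace, read_vt_series, read_xyz_frames)
from .synthetic import (LUTEOLIN_DHFUS_J_MOL, fixtures_luteolin_pvp,
                        gen_dissolution, gen_hbond_configuration,
                        gen_melting_depression, gen_vt_series)
from .thermal import analyze_tga, classify_gfa, tg_miscibility_verdict
from .trajectory import estimate_tg_from_volume, find_hbonds, radial_distribution

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

_STAGE_ORDER = ("hsp", "chi", "dgmix", "gfa", "tg_verdict", "tga",
                "rdf", "hbonds", "tgfit", "dissolution")

_TOP_KEYS = {"seed", "outdir", "stages"}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    seed: int
    stages: dict[str, dict[str, Any]]
    outdir: str | None = None

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        stages = dict(raw.get("stages", {}))
        bad = set(stages) - set(_STAGE_ORDER)
        if bad:
            raise ParseError(f"unknown stages: {sorted(bad)}")
        for name, params in stages.items():
            if params is None:
                stages[name] = {}
            elif not isinstance(params, Mapping):
                raise ParseError(f"stage {name!r}: parameters must be a mapping")
            else:
                stages[name] = dict(params)
        for name, params in stages.items():
            path = params.get("path")
            if path is not None and not Path(path).exists():
                raise ParseError(f"stage {name!r}: input path {path!r} does not exist")
        return cls(seed=int(raw.get("seed", 0)), stages=stages,
                   outdir=raw.get("outdir"))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, Mapping):
            raise ParseError(f"{path}: config must be a mapping")
        return cls.from_mapping(raw)

    def canonical_json(self) -> str:
        return json.dumps({"seed": self.seed, "stages": self.stages},
                          sort_keys=True, separators=(",", ":"))

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunReport:
    results: dict[str, Any]
    failures: dict[str, str]
    provenance: dict[str, Any]

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        d = json.loads(text)
        return cls(d["results"], d["failures"], d["provenance"])

    def payload_json(self) -> str:
        """Deterministic part (no timestamp) for equality comparisons."""
        return json.dumps({"results": self.results, "failures": self.failures,
                           "config_hash": self.provenance["config_hash"]},
                          sort_keys=True)


# --------------------------------------------------------------------------
# stage runners
# --------------------------------------------------------------------------

def _stage_hsp(params: dict, seed: int) -> dict:
    if params.get("source") == "fixture":
        fx = fixtures_luteolin_pvp()
        hsp_a, hsp_b = fx.lut_hansen, fx.pvp_hansen
        ids = ("luteolin", "PVP")
    else:
        from .group_contribution import GroupInventory
        table = load_default_group_table()
        invs = []
        for key in ("api", "polymer"):
            spec = params[key]
            inv = GroupInventory(spec["species_id"],
                                 tuple((e["group"], int(e["n"])) for e in spec["entries"]),
                                 spec.get("basis", "per_molecule"))
            invs.append(hansen_from_inventory(inv, table, spec.get("molar_volume")))
        hsp_a, hsp_b = invs
        ids = (params["api"]["species_id"], params["polymer"]["species_id"])
    verdict = classify_miscibility_delta(hsp_a.delta_t, hsp_b.delta_t)
    return {
        "api": {"species_id": ids[0], **dataclasses.asdict(hsp_a)},
        "polymer": {"species_id": ids[1], **dataclasses.asdict(hsp_b)},
        "delta_delta_t": verdict.delta_delta_t,
        "verdict": verdict.label,
    }


def _chi_series(params: dict, seed: int) -> MeltingDepressionSeries:
    if "generate" in params:
        g = dict(params["generate"])
        return gen_melting_depression(
            chi_true=g["chi_true"], m=g.get("m", 1000.0),
            dhfus=g.get("dhfus", LUTEOLIN_DHFUS_J_MOL),
            tm_pure=g.get("tm_pure", 616.35),
            phis=g.get("phis", [0.05, 0.10, 0.15, 0.20, 0.25, 0.30]),
            noise_sd_k=g.get("noise_sd_k", 0.0), seed=seed)
    import pandas as pd
    df = pd.read_csv(params["path"])
    meta = json.loads(Path(params["meta"]).read_text())
    if "tm_k" in df.columns:
        points = tuple(zip(df["phi_polymer"].astype(float), df["tm_k"].astype(float)))
        return MeltingDepressionSeries(meta["tm_pure_k"], meta["dhfus_j_mol"],
                                       meta["m"], points)
    points_c = tuple(zip(df["phi_polymer"].astype(float), df["tm_c"].astype(float)))
    return MeltingDepressionSeries.from_celsius(meta["tm_pure_c"],
                                                meta["dhfus_j_mol"], meta["m"],
                                                points_c)


def _stage_chi(params: dict, seed: int) -> dict:
    series = _chi_series(params, seed)
    fit = fit_chi(series)
    return dataclasses.asdict(fit)


def _stage_dgmix(params: dict, seed: int, upstream: dict) -> dict:
    chi = params.get("chi")
    if chi is None:
        chi = upstream.get("chi", {}).get("chi")
    if chi is None:
        raise ParseError("dgmix: no chi given and no chi stage result available")
    import numpy as np
    n = int(params.get("n_grid", 99))
    grid = np.linspace(0.0, 1.0, n + 2)[1:-1]
    curve = mixing_free_energy_curve(chi, params.get("m", 1000.0), grid)
    return {"chi": curve.chi, "m": curve.m,
            "phi_drug": [float(x) for x in curve.phi_drug],
            "dg_over_rt": [float(x) for x in curve.dg_over_rt],
            "all_negative": bool((curve.dg_over_rt < 0).all())}


def _stage_gfa(params: dict, seed: int) -> dict:
    if params.get("source") == "fixture":
        cycle = fixtures_luteolin_pvp().lut_gfa_cycle
    else:
        cycle = read_dsc_cycle(params["path"])
    return {"gfa_class": classify_gfa(cycle).value}


def _stage_tg_verdict(params: dict, seed: int) -> dict:
    tgs = params.get("tg_temperatures_c")
    if tgs is None:
        tgs = [fixtures_luteolin_pvp().blend_tgs_c[0]]
    return {"tg_temperatures_c": list(tgs),
            "verdict": tg_miscibility_verdict(tgs, params.get("tolerance_c", 2.0))}


def _stage_tga(params: dict, seed: int) -> dict:
    trace = read_tga_trace(params["path"])
    loss, onset = analyze_tga(trace, params.get("early_cutoff_c", 120.0),
                              params.get("loss_threshold_pct", 2.0))
    return {"initial_loss_pct": loss, "decomposition_onset_c": onset}


def _hbond_frame(params: dict, seed: int):
    if "generate" in params:
        g = dict(params["generate"])
        return gen_hbond_configuration(g.get("n_planted", 5), g.get("n_decoys", 5),
                                       g.get("box_edge", 40.0), seed)
    return read_xyz_frames(params["path"])[int(params.get("frame", 0))]


def _stage_rdf(params: dict, seed: int) -> dict:
    if "generate" in params:
        frames = [_hbond_frame(params, seed)]
    else:
        frames = read_xyz_frames(params["path"])
    profile = radial_distribution(
        frames, parse_selection(params.get("sel_a", "all")),
        parse_selection(params.get("sel_b", "all")),
        dr=params.get("dr", 0.05), r_max=params.get("r_max"))
    g = profile.g_values
    import numpy as np
    peak = int(np.argmax(g))
    return {"dr": profile.dr, "n_bins": len(g),
            "peak_r": float(profile.r_centers[peak]),
            "peak_g": float(g[peak])}


def _stage_hbonds(params: dict, seed: int) -> dict:
    frame = _hbond_frame(params, seed)
    records = find_hbonds(frame, params.get("d_max", 2.5),
                          params.get("angle_min", 90.0))
    return {"n_hbonds": len(records),
            "records": [dataclasses.asdict(r) for r in records]}


def _stage_tgfit(params: dict, seed: int) -> dict:
    if "generate" in params:
        g = dict(params["generate"])
        series = gen_vt_series(tg_true=g.get("tg_true", 460.0),
                               noise_rel=g.get("noise_rel", 0.0), seed=seed)
    else:
        series = read_vt_series(params["path"])
    est = estimate_tg_from_volume(series)
    return {"tg_k": est.tg, "degenerate": est.degenerate,
            "rubbery_slope": est.rubbery_line[0], "glassy_slope": est.glassy_line[0]}


def _stage_dissolution(params: dict, seed: int) -> dict:
    cs = params.get("cs", 5.7)
    if "generate" in params:
        g = dict(params["generate"])
        times = g.get("times", [5, 15, 30, 45, 60, 90, 120, 240])
        fold = g.get("fold", 6.0)
        ref = gen_dissolution(cs, g.get("k_rise", 0.2), 0.0, cs, times,
                              seed=seed, sample_id="crystalline")
        asd = gen_dissolution(fold * cs, g.get("k_rise", 0.2),
                              g.get("k_precip", 0.0), cs, times,
                              seed=seed + 1, sample_id="asd")
        profiles = {"crystalline": ref, "asd": asd}
        reference_id = "crystalline"
    else:
        profiles = read_concentration_profiles(params["path"])
        reference_id = params.get("reference")
    reference = profiles.get(reference_id) if reference_id else None
    out: dict[str, Any] = {"profiles": {}}
    for sid, prof in sorted(profiles.items()):
        ref = reference if (reference is not None and sid != reference_id) else None
        out["profiles"][sid] = dataclasses.asdict(profile_metrics(prof, cs, ref))
    if len(profiles) >= 2:
        out["ranking"] = compare_inhibitors(profiles, cs)
    return out


_RUNNERS = {
    "hsp": _stage_hsp, "chi": _stage_chi, "gfa": _stage_gfa,
    "tg_verdict": _stage_tg_verdict, "tga": _stage_tga, "rdf": _stage_rdf,
    "hbonds": _stage_hbonds, "tgfit": _stage_tgfit,
    "dissolution": _stage_dissolution,
}


def run_pipeline(config: RunConfig) -> RunReport:
    results: dict[str, Any] = {}
    failures: dict[str, str] = {}
    for name in _STAGE_ORDER:
        if name not in config.stages:
            continue
        params = config.stages[name]
        try:
            if name == "dgmix":
                results[name] = _stage_dgmix(params, config.seed, results)
            else:
                results[name] = _RUNNERS[name](params, config.seed)
        except AsdScreenError as e:
            failures[name] = f"{type(e).__name__}: {e}"
    report = RunReport(results, failures, {
        "config_hash": config.hash(),
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    })
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
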