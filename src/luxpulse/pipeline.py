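"""End-to-end pipeline: simulate -> analyze -> events -> response.

A single YAML/JSON config drives all stages; every output is plain CSV or
JSON so each stage can be inspected and re-run independently, and a
manifest records the config hash, seed, and package version so a run can
be reproduced bit-for-bit.

Derivative-based series (growth rate, deconvolved activity) are computed
on the full grid but the first and last half smoothing window are excluded
from event analysis: the one-sided endpoint fits have inflated variance
and can fabricate terminal events.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .events import (
    correlation_signs,
    define_T0,
    detect_bursts,
    detect_pauses,
    match_events,
    phase_offset,
)
from .kinetics import activity_deconvolved, activity_naive, growth_rate
from .plate import align_replicates, blank_correct, from_run, write_plate_csv
from .response import TransitionModel, simulate_transitions
from .scenarios import Scenario, bundled_scenario, load_scenario
from .simulate import render_plate_run, simulate_diauxic_growth

__all__ = ["default_config", "run_pipeline", "analyze_run"]

_ANALYSIS_KEYS = {"estimator", "window", "degree", "half_life"}
_EVENTS_KEYS = {"channel", "reference_channel", "min_depth", "min_width",
                "min_prominence", "merge_radius", "max_lag", "phase_window_start"}
_TRANSITIONS_KEYS = {"channel", "lambda0", "m", "K_c", "n_cells", "query_times"}
_TOP_KEYS = {"scenario", "seed", "wells", "blank_wells", "analysis", "events",
             "transitions"}


def default_config() -> dict:
    """The bundled sporulation-medium pipeline configuration."""
    return {
        "scenario": "dsm",
        "seed": 1,
        "wells": 2,
        "blank_wells": 2,
        "analysis": {"estimator": "deconvolved", "window": 11, "degree": 2,
                     "half_life": 0.1},
        "events": {"channel": "spo0A", "reference_channel": "rrnB",
                   "min_depth": 0.2, "min_width": 0.1, "min_prominence": 0.15,
                   "merge_radius": 0.15, "max_lag": 0.3,
                   "phase_window_start": 0.5},
        "transitions": {"channel": "comK", "lambda0": 0.001, "m": 3.0,
                        "K_c": 0.5, "n_cells": 20000,
                        "query_times": [0.65, 3.4]},
    }


def _check_keys(section: Mapping, allowed: set[str], path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")


def _load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text)
    if not isinstance(config, Mapping):
        raise ConfigurationError("pipeline config must be a mapping")
    _check_keys(config, _TOP_KEYS, "config")
    merged = default_config()
    for key in ("analysis", "events", "transitions"):
        if key in config:
            section = dict(config[key])
            _check_keys(section, globals()[f"_{key.upper()}_KEYS"], f"config.{key}")
            merged[key].update(section)
    for key in ("scenario", "seed", "wells", "blank_wells"):
        if key in config:
            merged[key] = config[key]
    ana = merged["analysis"]
    if ana["estimator"] not in ("naive", "deconvolved"):
        raise ConfigurationError(
            "config.analysis.estimator must be 'naive' or 'deconvolved'")
    if ana["estimator"] == "deconvolved" and not ana.get("half_life"):
        raise ConfigurationError(
            "config.analysis.half_life is required when estimator = 'deconvolved'")
    return merged


def _resolve_scenario(ref: str | Scenario) -> Scenario:
    if isinstance(ref, Scenario):
        return ref
    if Path(str(ref)).suffix in (".yaml", ".yml", ".json"):
        return load_scenario(ref)
    return bundled_scenario(str(ref))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_json(path: Path, payload: Any) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2))


def analyze_run(run, config: Mapping | None = None,
                half_life: float | None = None) -> dict:
    """Blank-correct, average replicates, and estimate mu-hat and activity.

    Returns a dict with the trimmed common time grid, per-promoter OD and
    activity series, and the growth-rate series of each promoter group.
    ``run`` may be a :class:`~luxpulse.simulate.PlateRun` or a
    :class:`~luxpulse.plate.PlateTable` whose provenance carries a
    ``well_map`` and ``blank_wells``.
    """
    cfg = _load_config(dict(config) if config else {})["analysis"]
    if half_life is not None:
        cfg = {**cfg, "half_life": half_life}
    meta = run.metadata if hasattr(run, "metadata") else run.provenance
    well_map = meta.get("well_map")
    if not well_map:
        raise ConfigurationError("analyze_run: metadata lacks a well_map")
    table = from_run(run) if hasattr(run, "metadata") else run
    blanks = meta.get("blank_wells") or []
    if blanks:
        table = blank_correct(table, blanks)
    groups: dict[str, list[str]] = {}
    for well, prom in well_map.items():
        groups.setdefault(prom, []).append(well)
    agg = align_replicates(table, groups)

    window, degree = int(cfg["window"]), int(cfg["degree"])
    trim = window // 2
    out: dict[str, Any] = {"estimator": cfg["estimator"], "window": window,
                           "degree": degree, "channels": {}}
    delta = None
    if cfg["estimator"] == "deconvolved":
        delta = float(np.log(2) / cfg["half_life"])
        out["delta"] = delta
    sl = slice(trim, -trim if trim else None)
    for prom, wells in groups.items():
        sub = agg[agg["group"] == prom]
        od = sub[sub["channel"] == "OD600"].sort_values("time_h")
        rlu = sub[sub["channel"] == "RLU"].sort_values("time_h")
        t = od["time_h"].to_numpy()
        od_v = od["mean"].to_numpy()
        rlu_v = rlu["mean"].to_numpy()
        mu = growth_rate(t, od_v, window=window, degree=degree)
        if cfg["estimator"] == "deconvolved":
            est = activity_deconvolved(t, rlu_v, od_v, delta,
                                       window=window, degree=degree)
        else:
            est = activity_naive(t, rlu_v, od_v)
        out["channels"][prom] = {
            "time": t[sl], "od": od_v[sl], "rlu": rlu_v[sl],
            "mu": mu.value[sl], "activity": est.value[sl],
            "n_wells": len(wells),
        }
    return out


def _events_stage(analysis: dict, cfg: Mapping) -> dict:
    channel = cfg["channel"]
    if channel not in analysis["channels"]:
        raise ConfigurationError(f"events channel {channel!r} not in analysis")
    ch = analysis["channels"][channel]
    t = np.asarray(ch["time"])
    mu = np.asarray(ch["mu"])
    act = np.asarray(ch["activity"])
    t0 = define_T0(t, mu)
    pauses = detect_pauses(t, mu, min_depth=cfg["min_depth"],
                           min_width=cfg["min_width"], t_max=t0)
    bursts = detect_bursts(t, act, min_prominence=cfg["min_prominence"],
                           merge_radius=cfg["merge_radius"])
    matches = match_events(pauses, bursts, max_lag=cfg["max_lag"])
    phase = phase_offset(t, mu, act, window=(cfg["phase_window_start"], t0),
                         t0=t0)
    activities = {name: np.asarray(c["activity"])
                  for name, c in analysis["channels"].items()}
    signs = correlation_signs(t, mu, activities,
                              window=(cfg["phase_window_start"], t0))
    return {
        "channel": channel,
        "T0": t0, "T1": t0 + 1.0, "T2": t0 + 2.0,
        "pauses": [asdict(p) for p in pauses],
        "bursts": [asdict(b) for b in bursts],
        "n_pauses": len(pauses),
        "n_bursts": len(bursts),
        "pairs": [{"pause_time": p.time, "burst_time": b.time, "lag": lag}
                  for p, b, lag in matches.pairs],
        "unmatched_bursts": [asdict(b) for b in matches.unmatched_bursts],
        "phase": asdict(phase),
        "correlation_signs": signs,
    }


def _response_stage(analysis: dict, cfg: Mapping, seed: int) -> dict:
    channel = cfg["channel"]
    if channel not in analysis["channels"]:
        raise ConfigurationError(f"transitions channel {channel!r} not in analysis")
    ch = analysis["channels"][channel]
    t = np.asarray(ch["time"])
    act = np.maximum(np.asarray(ch["activity"]), 0.0)
    # the hazard operates on the biological activity scale, not instrument
    # RLU: normalize by the light coefficient recorded with the run if any
    scale = cfg.get("activity_scale", 1.0)
    model = TransitionModel(lambda0=cfg["lambda0"], m=cfg["m"], K_c=cfg["K_c"])
    q = list(cfg["query_times"])
    _, counts = simulate_transitions(t, act * scale, model,
                                     n_cells=int(cfg["n_cells"]),
                                     seed=seed, query_times=q)
    return {
        "channel": channel,
        "n_cells": int(cfg["n_cells"]),
        "model": asdict(model),
        "query_times": q,
        "transitioned": [int(c) for c in counts],
        "fraction_pct": [100.0 * c / cfg["n_cells"] for c in counts],
    }


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path) -> Path:
    """Execute simulate -> analyze -> events -> response and write outputs.

    Writes ``run.csv`` (+ metadata sidecar), ``analysis.json``,
    ``events.json``, ``response.json`` and ``manifest.json`` under
    ``out_dir``; returns the output directory.  Deterministic for a fixed
    config and seed.
    """
    t_start = _time.time()
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = _resolve_scenario(cfg["scenario"])
    seed = int(cfg["seed"])

    traj = simulate_diauxic_growth(scenario)
    run = render_plate_run(traj, scenario, n_replicate_wells=int(cfg["wells"]),
                           seed=seed, n_blank_wells=int(cfg["blank_wells"]))
    write_plate_csv(run, out / "run.csv")

    # the deconvolution must use the reporter the plate run was produced
    # with; the config value is the analyst's (possibly wrong) belief
    analysis = analyze_run(run, {"analysis": cfg["analysis"]})
    _write_json(out / "analysis.json", analysis)

    events = _events_stage(analysis, cfg["events"])
    _write_json(out / "events.json", events)

    # an independent stream for the single-cell stage, still seed-derived
    response = _response_stage(
        {"channels": analysis["channels"]},
        {**cfg["transitions"],
         "activity_scale": 1.0 / scenario.reporter.light_coeff},
        seed=seed + 1,
    )
    _write_json(out / "response.json", response)

    cfg_json = json.dumps(_jsonable(cfg), sort_keys=True)
    manifest = {
        "command": "run",
        "package_version": __version__,
        "seed": seed,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "scenario": scenario.name,
        "outputs": ["run.csv", "run.meta.json", "analysis.json",
                    "events.json", "response.json"],
        "started_unix": t_start,
        "wall_time_s": _time.time() - t_start,
    }
    _write_json(out / "manifest.json", manifest)
    return out
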