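"""End-to-end orchestration: simulate -> render -> analyze -> summarize.

A run is fully determined by a flat ``key = value`` configuration and a
master seed: the same pair reproduces every trajectory, camera noise
draw and bootstrap replicate byte for byte.  Artifacts written to the
output directory: per-trace events (CSV), cohort summary (JSON) and a
provenance record (config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .events import COMPLETE, DetectionConfig, EventSet, analyze_trace
from .fits import fit_stall_levels
from .kinetics import KineticParams, ReactionConditions, simulate_cohort
from .render import CalibrationCurve, FretTrace, NoiseModel, render_trace, write_trace
from .stats import CohortSummary, bootstrap_counts
from .substrate import SubstrateSpec, get_substrate, make_substrate

__all__ = ["read_config", "run_pipeline", "summarize_events", "events_to_frame"]

_PARAM_KEYS = {f.name for f in dataclasses.fields(KineticParams)}
_COND_KEYS = {f.name for f in dataclasses.fields(ReactionConditions)}


def _coerce(value: str):
    v = value.strip()
    low = v.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v


def read_config(path) -> Dict:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    config: Dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = line.split("=", 1)
        config[key.strip()] = _coerce(value)
    return config


def _build(config: Dict) -> Tuple[SubstrateSpec, ReactionConditions, KineticParams]:
    name = str(config.get("substrate", "AT40"))
    if name == "custom":
        gc = config.get("gc_positions", "")
        gc_positions = [int(p) for p in str(gc).split(",") if str(p).strip()]
        substrate = make_substrate(int(config.get("length", 40)), gc_positions)
    else:
        substrate = get_substrate(name)
    cond_kwargs = {k: config[k] for k in _COND_KEYS if k in config}
    if "dnag" in config:
        cond_kwargs["dnag_present"] = bool(config["dnag"])
    param_kwargs = {k: config[k] for k in _PARAM_KEYS if k in config}
    return substrate, ReactionConditions(**cond_kwargs), KineticParams(**param_kwargs)


def events_to_frame(events: List[EventSet]) -> pd.DataFrame:
    """Tidy per-trace table of scored events."""
    rows = []
    for i, ev in enumerate(events):
        rows.append({
            "trace": i,
            "outcome": ev.outcome,
            "t_init_s": ev.t_init,
            "t_unw_s": ev.t_unw,
            "slip_count": ev.slip_count,
            "n_stalls": len(ev.stalls),
            "stall_levels": ";".join(f"{s.level:.4f}" for s in ev.stalls),
            "stall_lifetimes_s": ";".join(f"{s.lifetime:.4f}" for s in ev.stalls),
        })
    return pd.DataFrame(rows)


def summarize_events(events: List[EventSet], seed: int = 0,
                     mixture_components: Optional[int] = None,
                     max_components: int = 4) -> CohortSummary:
    """Aggregate scored traces into a :class:`CohortSummary`.

    The completion fraction uses traces with protein activity as the
    denominator.  The mean slip count (over active traces) carries a
    bootstrap percentile interval; stall levels are pooled and, when at
    least 30 are available, summarized by a Gaussian mixture.
    """
    active = [e for e in events if e.outcome != "no_activity"]
    complete = [e for e in active if e.outcome == COMPLETE]
    slips = [e.slip_count for e in active]
    levels = [s.level for e in active for s in e.stalls]
    t_inits = [e.t_init for e in active if e.t_init is not None]
    t_unws = [e.t_unw for e in complete if e.t_unw is not None]

    if slips:
        boot = bootstrap_counts(slips, n_boot=1000, seed=seed)
        slip_mean, slip_ci = boot.mean, (boot.ci_low, boot.ci_high)
    else:
        slip_mean, slip_ci = 0.0, (0.0, 0.0)

    mixture = None
    if len(levels) >= 30:
        try:
            gm = fit_stall_levels(levels, max_components=max_components,
                                  n_components=mixture_components, seed=seed)
            mixture = {"n_components": gm.n_components,
                       "means": list(gm.means), "sigmas": list(gm.sigmas),
                       "weights": list(gm.weights), "bic": gm.bic}
        except ValueError:
            mixture = None

    return CohortSummary(
        n_traces=len(events),
        n_active=len(active),
        n_complete=len(complete),
        complete_fraction=len(complete) / len(active) if active else 0.0,
        mean_slip_count=slip_mean,
        slip_ci=slip_ci,
        mean_t_init=float(np.mean(t_inits)) if t_inits else None,
        mean_t_unw=float(np.mean(t_unws)) if t_unws else None,
        stall_levels=tuple(levels),
        stall_mixture=mixture,
    )


def run_pipeline(config, seed: Optional[int] = None,
                 out_dir: Optional[Path] = None,
                 save_traces: bool = False) -> CohortSummary:
    """Execute simulate -> render -> analyze -> summarize from a config.

    ``config`` is a mapping or a path to a flat ``key = value`` file.
    Recognized keys: ``substrate`` (AT40/1GC/2GC/3GC/custom),
    ``n_traces``, ``seed``, ``horizon``, ``frame_interval``,
    ``total_intensity``, ``noise_sigma``, ``background``,
    ``mixture_components`` plus any :class:`KineticParams` /
    :class:`ReactionConditions` field (and ``dnag`` as a shorthand for
    ``dnag_present``).  ``seed`` overrides the config's seed.
    """
    if not isinstance(config, dict):
        config = read_config(config)
    substrate, conditions, params = _build(config)
    master_seed = int(seed if seed is not None else config.get("seed", 0))
    n_traces = int(config.get("n_traces", 100))
    horizon = float(config.get("horizon", 120.0))
    frame_interval = float(config.get("frame_interval", 0.1))
    noise = NoiseModel(
        total_intensity=float(config.get("total_intensity", 1000.0)),
        sigma=float(config.get("noise_sigma", 30.0)),
        background=float(config.get("background", 100.0)),
    )
    calibration = CalibrationCurve()
    detect = DetectionConfig()

    trajectories = simulate_cohort(substrate, conditions, params, n_traces,
                                   master_seed, horizon=horizon)
    render_seeds = np.random.SeedSequence(master_seed + 1).generate_state(n_traces)
    events: List[EventSet] = []
    traces: List[FretTrace] = []
    for traj, rs in zip(trajectories, render_seeds):
        trace = render_trace(traj, calibration, noise, frame_interval,
                             seed=int(rs))
        events.append(analyze_trace(trace, config=detect))
        if save_traces:
            traces.append(trace)

    mixture_components = config.get("mixture_components")
    summary = summarize_events(
        events, seed=master_seed,
        mixture_components=int(mixture_components) if mixture_components else None,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        events_to_frame(events).to_csv(out_dir / "events.csv", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=1, sort_keys=True)
        config_blob = json.dumps(config, sort_keys=True, default=str)
        provenance = {
            "config": config,
            "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
            "seed": master_seed,
            "version": __version__,
            "substrate": substrate.name,
            "thresholds": dataclasses.asdict(detect),
        }
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, sort_keys=True, default=str)
        if save_traces:
            trace_dir = out_dir / "traces"
            trace_dir.mkdir(exist_ok=True)
            for i, trace in enumerate(traces):
                write_trace(trace, trace_dir / f"trace_{i:04d}.tsv")
    return summary
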