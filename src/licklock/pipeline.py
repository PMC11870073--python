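"""Config-driven end-to-end orchestration and summary reporting.

A pipeline run takes a session (read from disk or simulated), applies the
enabled stages per cell — validity, bout/lick modulation, phase coherence,
autocorrelogram power, rosette kinematics, decoding, perturbation analysis
— and assembles a machine-readable summary (per-cell table plus population
fractions). Re-running with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from . import decoder, kinematics, modulation, rhythm, synth
from .core_io import Session, segment_bouts, validate_cell
from . import perturbation

logger = logging.getLogger("licklock")

#: defaults; every value is either the study's stated parameter or a
#: documented package decision (see docs/methods.md)
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "validate": True,
        "modulate": True,
        "rhythm": True,
        "rosette": True,
        "decode": True,
        "adapt": True,
    },
    "simulate": None,  # or {"duration": s, "n_cells": int, "cell_spec": {...}, ...}
    "bout_max_gap_s": 0.5,
    "psth_bin_s": 0.010,
    "z_threshold": 3.0,
    "min_trials": 20,
    "coherence_threshold": 0.5,
    "decoder_params": dict(decoder.DEFAULT_MODEL_PARAMS),
}


def _merge_config(config: Optional[dict]) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in config.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict) and k != "simulate":
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def simulate_session(sim_cfg: dict, seed: int):
    """Build a synthetic session from a simulate-config block."""
    behaviour = synth.BehaviourSpec(**sim_cfg.get("behaviour", {}))
    cell_cfgs = sim_cfg.get("cells")
    if cell_cfgs is None:
        cell_cfgs = [sim_cfg.get("cell_spec", {})] * int(sim_cfg.get("n_cells", 1))
    specs = [synth.CellSpec(**c) for c in cell_cfgs]
    return synth.generate_session(
        behaviour,
        specs,
        duration=float(sim_cfg.get("duration", 600.0)),
        n_port_trials=int(sim_cfg.get("n_port_trials", 0)),
        opto_plan=sim_cfg.get("opto_plan"),
        seed=seed,
    )


def run_pipeline(config: Optional[dict] = None, session: Optional[Session] = None) -> dict:
    """Run the enabled stages and return the summary dict.

    ``session`` overrides any simulate block; otherwise the config must
    request simulation. The summary carries one entry per cell plus
    population fractions and collected warnings.
    """
    cfg = _merge_config(config)
    seed = int(cfg["seed"])
    warnings: list = []
    if session is None:
        if not cfg.get("simulate"):
            raise ValueError("no session given and no simulate block in config")
        session, _ = simulate_session(cfg["simulate"], seed)
    licks = session.licks
    bouts = segment_bouts(licks, cfg["bout_max_gap_s"])
    stages = cfg["stages"]
    per_cell = {}
    for cell in session.cells:
        entry: dict = {"grid_row": cell.grid_row, "grid_col": cell.grid_col}
        logger.info("cell %s: %d SS, %d CS", cell.cell_id, cell.ss_times.size,
                    cell.cs_times.size)
        if stages.get("validate"):
            rep = validate_cell(cell, n_trials=licks.n_licks,
                                min_trials=cfg["min_trials"])
            entry["valid"] = rep.passed
            if not rep.passed:
                warnings.append(f"{cell.cell_id}: failed validity")
        if stages.get("modulate") and len(bouts) >= cfg["min_trials"]:
            for which in ("start", "end"):
                r = modulation.bout_transition_response(
                    cell.cs_times, bouts, which,
                    session_duration=licks.session_duration,
                    min_trials=cfg["min_trials"],
                )
                entry[f"cs_bout_{which}_peak_z"] = r.peak_z
                entry[f"cs_bout_{which}_significant"] = r.significant
        if stages.get("rhythm"):
            pmap = rhythm.build_phase_map(licks, bouts)
            for label, times in (("ss", cell.ss_times), ("cs", cell.cs_times)):
                c = rhythm.lick_coherence(times, licks, pmap)
                entry[f"msc_{label}"] = c.msc
                entry[f"phase_{label}"] = c.phase
                entry[f"coherent_{label}"] = c.coherent
            p = rhythm.autocorr_power(cell.ss_times, licks, bouts)
            entry["power_in_bout"] = p.power_at_pref_in
            entry["power_out_bout"] = p.power_at_pref_out
        if stages.get("rosette") and licks.has_endpoints():
            try:
                rosette = kinematics.build_rosette(licks)
                lat = kinematics.lateral_comparison(cell, licks, rosette)
                entry["lateral_mean_ipsi"] = lat.mean_ipsi
                entry["lateral_mean_contra"] = lat.mean_contra
            except ValueError as err:
                warnings.append(f"{cell.cell_id}: rosette skipped ({err})")
        if stages.get("decode"):
            rep = decoder.decode_cell(licks, cell, seed=seed,
                                      model_params=cfg["decoder_params"])
            entry["acc_bout"] = rep.acc_bout
            entry["acc_interbout"] = rep.acc_interbout
            entry["predictivity"] = rep.predictivity
            entry["attribution"] = rep.attribution
        if stages.get("adapt") and session.port_trials:
            tls = perturbation.index_trial_licks(session.port_trials, licks)
            try:
                right, centre, sel = perturbation.cs_direction_selectivity(
                    cell, session.port_trials, licks, min_trials=cfg["min_trials"]
                )
                entry["cs_move_peak_z_right"] = right.peak_z
                entry["cs_move_peak_z_centre"] = centre.peak_z
                entry["cs_move_selectivity"] = sel
            except ValueError as err:
                warnings.append(f"{cell.cell_id}: cs_move skipped ({err})")
        per_cell[cell.cell_id] = entry

    n_cells = len(per_cell)
    fractions = {}
    for key in ("cs_bout_start_significant", "cs_bout_end_significant",
                "coherent_ss", "coherent_cs"):
        vals = [e[key] for e in per_cell.values() if key in e]
        if vals:
            fractions[key] = float(np.mean(vals))
    preds = [e.get("predictivity") for e in per_cell.values() if "predictivity" in e]
    if preds:
        fractions["predictive_or_better"] = float(
            np.mean([p != "non_predictive" for p in preds])
        )
    summary = {
        "seed": seed,
        "n_cells": n_cells,
        "n_licks": licks.n_licks,
        "n_bouts": len(bouts),
        "cells": per_cell,
        "population_fractions": fractions,
        "warnings": warnings,
    }
    return summary


def write_summary(summary: dict, out_path: str | Path) -> None:
    Path(out_path).write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=_json_default)
    )


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
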