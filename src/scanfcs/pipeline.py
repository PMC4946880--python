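"""End-to-end pipeline runner.

Executes the requested stages in dependency order

    simulate -> rics / pcf / nandb -> model -> sobol -> calibrate

on a single configuration (YAML or dict), logging seeds and QC outcomes.
A failed stage marks its dependents as skipped rather than aborting.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibrate as cal
from . import model as mdl
from . import nandb, pcf, rics, sobol
from .io import save_results
from .synthetic import (Geometry, PSFModel, ScanConfig, SpeciesSpec, Wall,
                        simulate_line_scan, simulate_raster)

__all__ = ["run_pipeline", "STAGES", "default_config"]

log = logging.getLogger("scanfcs")

STAGES = ("simulate", "rics", "pcf", "nandb", "model", "sobol", "calibrate")
_DEPS = {
    "rics": ("simulate",),
    "pcf": ("simulate",),
    "nandb": ("simulate",),
    "sobol": ("model",),
    "calibrate": ("model",),
}


def default_config() -> dict:
    """A small demonstration configuration (seconds, not minutes)."""
    return {
        "stages": ["simulate", "rics", "nandb", "model", "calibrate"],
        "seed": 0,
        "out_dir": "results",
        "scan": {"image_size": 64, "frame_count": 40, "pixel_size": 0.1},
        "line_scan": {"n_lines": 20000, "line_length": 32, "image_size": 32,
                      "pixel_size": 0.25, "line_time": 1.0},
        "psf": {"w0": 0.25, "wz": 0.75},
        "species": [{"label": "monomer", "diffusion_coefficient": 2.45,
                     "brightness_per_unit": 0.5, "count": 1500}],
        "background_rate": 0.05,
        "sobol": {"n": 64, "replicates": 2},
        "model": {"t_end": 48.0},
    }


def _scan_config(cfg: dict, key: str) -> ScanConfig:
    return ScanConfig.from_dict(cfg.get(key, {}))


def run_pipeline(config) -> dict:
    """Run the configured stages; returns a summary dict."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = {**default_config(), **config}
    stages = list(cfg["stages"])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {', '.join(unknown)}")

    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    psf = PSFModel(**cfg["psf"])
    summary: dict = {"seed": seed, "stages": {}}
    state: dict = {}

    def ready(stage):
        return all(summary["stages"].get(d, {}).get("ok") for d in
                   _DEPS.get(stage, ()))

    for stage in STAGES:
        if stage not in stages:
            continue
        if not ready(stage):
            summary["stages"][stage] = {"ok": False, "skipped": True,
                                        "reason": "dependency failed"}
            continue
        try:
            info = _run_stage(stage, cfg, state, psf, seed, out_dir)
            info["ok"] = True
        except Exception as exc:           # stage isolation by design
            log.exception("stage %s failed", stage)
            info = {"ok": False, "error": str(exc)}
        summary["stages"][stage] = info
    return summary


def _run_stage(stage, cfg, state, psf, seed, out_dir) -> dict:
    if stage == "simulate":
        scan_cfg = _scan_config(cfg, "scan")
        species = [SpeciesSpec(**s) for s in cfg["species"]]
        series = simulate_raster(species, psf, scan_cfg, seed=seed,
                                 background_rate=cfg["background_rate"])
        state["raster"] = series
        line_cfg = _scan_config(cfg, "line_scan")
        wall = Wall(line_cfg.line_length * line_cfg.pixel_size / 2, 1.0, 1.0)
        geom = Geometry.for_scan(line_cfg, psf, "line", walls=[wall])
        state["lines"] = simulate_line_scan(
            species, psf, line_cfg, seed=seed + 1,
            background_rate=cfg["background_rate"], geometry=geom,
            wall_column=line_cfg.line_length // 2)
        return {"frames": series.frame_count}

    if stage == "rics":
        filtered = rics.subtract_moving_average(state["raster"])
        acf = rics.compute_acf(filtered)
        fit = rics.fit_diffusion(acf, psf, state["raster"].config)
        save_results({"fit": {"D": fit.D, "G0": fit.G0,
                              "qc_pass": fit.qc_pass}},
                     out_dir, "rics", state["raster"].config, seed)
        return {"D": fit.D, "qc_pass": fit.qc_pass}

    if stage == "pcf":
        lines = state["lines"]
        prepared = pcf.prepare_carpet(lines)
        wall_col = pcf.locate_wall(lines.reference_before)
        calls = []
        for dr in pcf.STANDARD_DISTANCES:
            carpet = pcf.pair_correlation(prepared.analysis, dr, "forward")
            calls.append(pcf.detect_arch(carpet, wall_col, seed=seed))
        mi = pcf.movement_index([calls])
        save_results({"movement_index": {"mi": mi.mi, "calls": calls,
                                         "wall_column": wall_col}},
                     out_dir, "pcf", lines.config, seed)
        return {"mi": mi.mi, "wall_column": wall_col}

    if stage == "nandb":
        series = state["raster"]
        s = nandb.calibrate_sfactor(series)
        bmap = nandb.brightness_map(series, s_factor=s)
        eps_true = series.ground_truth["species"][0]["brightness_per_unit"]
        cursor = nandb.CursorSpec(s_factor=s, monomer_brightness=eps_true,
                                  cursor_size=0.8 * eps_true)
        cls = nandb.classify_oligomers(bmap, cursor)
        save_results({"classification": cls, "brightness": bmap.brightness},
                     out_dir, "nandb", series.config, seed)
        return {"s_factor": s, **cls}

    if stage == "model":
        params = mdl.default_params()
        traj = mdl.simulate(params, t_end=cfg["model"]["t_end"])
        metrics = mdl.steady_state_metrics(traj)
        state["params"] = params
        save_results({"trajectory": traj.to_frame(), "metrics": metrics},
                     out_dir, "model", None, seed)
        return {k: metrics[k] for k in
                ("steady_state_time", "homodimer_pct", "complex21_pct")}

    if stage == "sobol":
        params = state["params"]
        res = sobol.run_replicates(params, n=cfg["sobol"]["n"],
                                   n_replicates=cfg["sobol"]["replicates"],
                                   seed=seed)
        ranked = sobol.normalize_and_rank(res)
        table = pd.DataFrame(ranked["mean_normalized"],
                             index=ranked["parameters"],
                             columns=ranked["outcomes"]).reset_index(
                                 names="parameter")
        save_results({"indices": table}, out_dir, "sobol", None, seed)
        return {"influential": {k: list(v) for k, v in
                                ranked["influential"].items()}}

    if stage == "calibrate":
        params = state["params"]
        result = cal.estimate_parameters(params)
        save_results({"calibrated": {**result.params.to_dict(),
                                     "deviation": result.deviation,
                                     "success": result.success}},
                     out_dir, "calibrate", None, seed)
        return {"success": result.success,
                "homodimer_pct": result.achieved["homodimer_pct"],
                "complex21_pct": result.achieved["complex21_pct"]}

    raise ValueError(stage)
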