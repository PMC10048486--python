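"""Pipeline orchestration: simulate -> analyze -> report.

A single configuration document (YAML/JSON or a plain dict) drives the
whole run: synthetic movies are generated from a gelation schedule (or
real stacks loaded from disk), each movie passes through PIV, DVA and DDM,
the shared fitting module turns relaxation curves into (tau, beta) and
microscopic viscosities, and the rheology stage adds the Winter-Chambon
gel point when a moduli table is supplied.  Every stage writes its
artifacts to the output directory and a structured log line with counters
(clipped ISF values, invalid PIV blocks, rejected plateaus) — the
observability surface for the long-lag ensemble artifacts.

Determinism: every stochastic operation takes a sub-seed derived by a
documented rule — the SHA-256 of ``"{stage}:{global seed}"`` reduced
modulo 2^31 — so a rerun with an identical configuration is bit-identical
and the report hash is stable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import ddm, dva, fitting, piv, rheology, synthetic
from .exceptions import ConfigurationError, GelscopeError
from .movie_io import ImageStack, read_stack, write_stack

__all__ = ["GelationReport", "run_pipeline", "subseed", "load_config", "config_hash"]


def subseed(stage: str, seed: int) -> int:
    """Deterministic per-stage sub-seed: sha256("{stage}:{seed}") mod 2^31."""
    digest = hashlib.sha256(f"{stage}:{seed}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % 2**31


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


@dataclass
class GelationReport:
    """Per-elapsed-time observables plus run-level results.

    ``table`` has one row per movie: normalized mobility, DVA tau/beta,
    DDM tau/beta at the reference q, the microscopic viscosity from both
    routes (and their ratio), and the MSD exponent.  ``globals`` holds the
    PIV/DVA arrest time, the Winter-Chambon tc when rheology was supplied,
    the configuration hash and the seeds.
    """

    table: pd.DataFrame
    globals: dict
    counters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "globals": self.globals,
            "counters": self.counters,
            "rows": json.loads(self.table.to_json(orient="records")),
        }
        return json.dumps(payload, sort_keys=True, indent=1, default=str)

    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "report.csv", index=False)
        (outdir / "report.json").write_text(self.to_json())


def _build_schedule(cfg: dict) -> synthetic.GelationSchedule:
    if cfg.get("schedule", "acid_milk_default") == "acid_milk_default":
        return synthetic.GelationSchedule.acid_milk_default()
    stages = []
    for item in cfg["schedule"]:
        kind = item["motion"]["kind"]
        params = {k: v for k, v in item["motion"].items() if k != "kind"}
        stages.append(
            synthetic.Stage(
                elapsed_time=item["elapsed_time_min"],
                motion=synthetic.MotionModel(kind, **params),
                viscosity=item.get("viscosity_mpas", 1.0),
            )
        )
    return synthetic.GelationSchedule(
        stages=stages,
        probe_radius=cfg.get("probe_radius_um", synthetic.DEFAULT_PROBE_RADIUS_UM),
        temperature=cfg.get("temperature_k", synthetic.DEFAULT_TEMPERATURE_K),
    )


def _acquire_movies(config, outdir, log) -> Tuple[List[ImageStack], float, float]:
    """Return (stacks, probe_radius_um, temperature_K)."""
    movies_cfg = config.get("movies", {})
    probe_radius = config.get("probe_radius_um", synthetic.DEFAULT_PROBE_RADIUS_UM)
    temperature = config.get("temperature_k", synthetic.DEFAULT_TEMPERATURE_K)
    if "paths" in movies_cfg:
        stacks = [read_stack(p) for p in movies_cfg["paths"]]
        log("load_movies", n=len(stacks))
        return stacks, probe_radius, temperature
    syn = movies_cfg.get("synthetic", {})
    schedule = _build_schedule(syn)
    optics = synthetic.OpticsModel(**syn.get("optics", {}))
    pairs = synthetic.simulate_schedule(
        schedule,
        optics=optics,
        n_particles=syn.get("n_particles", 500),
        n_frames=syn.get("n_frames", 500),
        frame_interval=syn.get("frame_interval_s", 0.02),
        seed=subseed("simulate", config.get("seed", 0)),
    )
    stacks = []
    for stack, traj in pairs:
        stacks.append(stack)
        if outdir is not None:
            tag = f"t{stack.elapsed_time:g}min"
            write_stack(stack, outdir / f"movie_{tag}.tif")
            synthetic.write_trajectories_csv(traj, outdir / f"trajectories_{tag}.csv")
    log("simulate", n_movies=len(stacks), schedule=[s.elapsed_time for s in schedule.stages])
    return stacks, schedule.probe_radius, schedule.temperature


def run_pipeline(config, output_dir: Optional[str] = None) -> GelationReport:
    """Execute the full simulate -> PIV/DVA/DDM -> rheology -> report run.

    ``config`` is a dict or a path to a YAML/JSON document.  Stage
    failures on individual movies are caught, recorded in the counters and
    left as NaN rows; a partial-results manifest lists what completed.
    """
    config = load_config(config)
    if not isinstance(config, dict):
        raise ConfigurationError("configuration must be a mapping")
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir or config.get("output_dir", "gelscope_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list = []
    counters: dict = {"plateau_fallbacks": 0, "stage_failures": []}

    def log(stage, **kw):
        line = {"stage": stage, **kw}
        log_lines.append(line)

    stacks, probe_radius, temperature = _acquire_movies(config, outdir, log)
    stacks.sort(key=lambda s: (s.elapsed_time is None, s.elapsed_time))
    elapsed = [s.elapsed_time for s in stacks]

    piv_cfg = config.get("piv", {})
    lag = piv_cfg.get("lag_s", 0.1)
    ddm_cfg = config.get("ddm", {})
    q_ref = ddm_cfg.get("q")  # None -> probe scale 2*pi/R

    rows = []
    fields_per_movie = []
    for stack in stacks:
        row: dict = {"elapsed_min": stack.elapsed_time}
        # --- PIV ---
        try:
            fields = piv.displacement_field(
                stack,
                lag=lag,
                block_size=piv_cfg.get("block_size", 32),
                search_radius=piv_cfg.get("search_radius", 8),
            )
            fields_per_movie.append(fields)
            pd.concat([f.to_frame() for f in fields]).to_csv(
                outdir / f"piv_t{stack.elapsed_time:g}min.csv", index=False
            )
        except GelscopeError as err:
            counters["stage_failures"].append(
                {"stage": "piv", "elapsed_min": stack.elapsed_time, "error": str(err)}
            )
            fields_per_movie.append(None)

        # --- DVA ---
        try:
            curve = dva.differential_variance_curve(stack, plateau="lag")
            if curve.plateau is None:
                counters["plateau_fallbacks"] += 1
                curve = dva.differential_variance_curve(stack, plateau="frame")
            curve = dva.order_parameter(curve)
            curve.to_frame().to_csv(
                outdir / f"dva_t{stack.elapsed_time:g}min.csv", index=False
            )
            fit = fitting.fit_stretched_exponential(curve.lags, curve.q_values)
            row["dva_tau_s"] = fit.tau
            row["dva_beta"] = fit.beta
            row["eta_dva_mpas"] = fitting.microscopic_viscosity(
                fit, probe_radius, temperature, method="dva"
            ).eta
        except GelscopeError as err:
            counters["stage_failures"].append(
                {"stage": "dva", "elapsed_min": stack.elapsed_time, "error": str(err)}
            )

        # --- DDM ---
        try:
            sf = ddm.structure_function(stack)
            sf = ddm.estimate_noise_and_amplitude(sf)
            isf = ddm.extract_isf(sf, q=q_ref, probe_radius=probe_radius)
            mask = (isf.f_values > -0.2) & (isf.f_values <= 1.2)
            fit = fitting.fit_stretched_exponential(
                isf.lags[mask], np.clip(isf.f_values[mask], -0.2, 1.2), q=isf.q
            )
            row["ddm_tau_s"] = fit.tau
            row["ddm_beta"] = fit.beta
            row["ddm_q_um_inv"] = isf.q
            row["eta_ddm_mpas"] = fitting.microscopic_viscosity(
                fit, probe_radius, temperature, method="ddm"
            ).eta
            msd = ddm.isf_to_msd(isf)
            row["msd_exponent"] = msd.exponent
            msd.to_frame().to_csv(
                outdir / f"msd_t{stack.elapsed_time:g}min.csv", index=False
            )
            counters[f"isf_clips_t{stack.elapsed_time:g}"] = isf.meta["n_clipped"]
        except GelscopeError as err:
            counters["stage_failures"].append(
                {"stage": "ddm", "elapsed_min": stack.elapsed_time, "error": str(err)}
            )
        if "eta_dva_mpas" in row and "eta_ddm_mpas" in row:
            row["eta_ratio_dva_over_ddm"] = row["eta_dva_mpas"] / row["eta_ddm_mpas"]
        rows.append(row)
        log("movie_done", elapsed_min=stack.elapsed_time)

    table = pd.DataFrame(rows)
    glob: dict = {
        "config_hash": config_hash(config),
        "seed": seed,
        "probe_radius_um": probe_radius,
        "temperature_k": temperature,
    }

    # --- Mobility curve and arrest time ---
    good = [f for f in fields_per_movie if f is not None]
    if len(good) == len(fields_per_movie) and len(good) >= 2:
        curve = piv.mobility_curve(fields_per_movie, elapsed)
        curve.to_frame().to_csv(outdir / "mobility_curve.csv", index=False)
        table["mobility"] = curve.values
        if len(elapsed) >= 4:
            cp = fitting.detect_changepoint(curve)
            glob["arrest_time_min"] = cp.changepoint
            glob["arrest_degenerate"] = cp.degenerate
        counters["piv_invalid_blocks"] = curve.meta["n_invalid_blocks"]

    # --- Rheology ---
    rheo_cfg = config.get("rheology")
    if rheo_cfg:
        if "path" in rheo_cfg:
            trace = rheology.read_rheo_csv(rheo_cfg["path"])
        else:
            syn = dict(rheo_cfg.get("synthetic", {}))
            syn.setdefault("seed", subseed("rheology", seed))
            trace = synthetic.synthesize_rheology(**syn)
        rheology.write_rheo_csv(trace, outdir / "rheology.csv")
        trace = rheology.loss_tangent(trace)
        gel = rheology.detect_gel_point_winter(trace)
        glob["tc_min"] = gel.tc
        glob["tan_delta_at_tc"] = gel.tan_delta_at_tc
        glob["tc_dispersion"] = gel.dispersion_at_tc
        try:
            fit_gp, fit_gpp, fit_tan = rheology.aging_power_laws(trace)
            glob["aging_exponent_storage"] = fit_gp.exponent
            glob["aging_exponent_loss"] = fit_gpp.exponent
            glob["aging_exponent_tan_delta"] = fit_tan.exponent
        except GelscopeError as err:
            counters["stage_failures"].append({"stage": "rheology_aging", "error": str(err)})
        log("rheology", tc_min=gel.tc)

    report = GelationReport(table=table, globals=glob, counters=counters)
    report.write(outdir)
    (outdir / "pipeline_log.jsonl").write_text(
        "\n".join(json.dumps(l, sort_keys=True, default=str) for l in log_lines)
    )
    manifest = sorted(p.name for p in outdir.iterdir())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report
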