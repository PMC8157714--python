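"""End-to-end pipeline: synthesize -> fickian fit -> SE table -> hopping
-> free volume, driven by a validated configuration.

Every run writes a resolved copy of the configuration next to the
outputs and a machine-readable JSON report of the key quantities
(D_w_org, alpha, timescales, barriers, occupied fractions).  All
randomness derives from the single global seed via named per-stage
substreams, so any stage re-run in isolation reproduces its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .cavity_hopping import (
    fit_hmm,
    hop_statistics,
    msd_diffusion,
    select_n_states,
    tst_barrier,
)
from .droplet_fickian import (
    ActivityModel,
    DiffusivityParameterization,
    fit_diffusivity,
    fit_kww,
)
from .free_volume import occupied_fraction
from .se_divergence import (
    ViscosityParameterization,
    build_table,
    divergence_orders,
    fit_fractional_exponent,
    se_predict,
)
from .synthetic_data import (
    gen_response_curve,
    gen_sphere_packing,
    gen_two_state_jump,
)

log = logging.getLogger("cavitydiff.pipeline")

STAGES = ("synth", "fickian", "se", "hop", "fv")


def stage_seed(global_seed: int, stage: str) -> int:
    """Named, stable per-stage substream of the global seed."""
    return int(
        np.random.SeedSequence(
            [int(global_seed), zlib.crc32(stage.encode())]
        ).generate_state(1)[0]
    )


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    stages: list = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    outdir: str = "pipeline_out"
    log_level: str = "INFO"
    synth: dict = field(default_factory=dict)
    fickian: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    hop: dict = field(default_factory=dict)
    fv: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {STAGES}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SYNTH_DEFAULTS = {
    "truth_coefficients": [-15.0, 6.0, -2.0],
    "rh_steps": [[70.0, 50.0], [50.0, 30.0], [30.0, 10.0]],
    "noise_sd": 0.005,
    "n_points": 100,
    "n_shells": 60,
    "initial_radius": 4.0e-6,
    "jump": {"k12": 1.0, "k21": 4.0, "dt": 1.0, "n_steps": 40000},
    "packing": {"n_spheres": 300, "radius": 0.15, "box": [4.0, 4.0, 4.0]},
}


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute the selected stages in dependency order.

    Returns the run report (also written as ``report.json``).  A stage
    failure is recorded in the report and later stages that depend on it
    are skipped; independent stages still run.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(name)s %(levelname)s %(message)s",
    )
    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump({"version": __version__, **config.to_dict()})
    )

    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    artifacts: dict = {}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        seed = stage_seed(config.seed, stage)
        log.info("stage %s (seed %d)", stage, seed)
        try:
            result = _STAGE_FUNCS[stage](config, seed, outdir, artifacts)
            report["stages"][stage] = {"status": "ok", **result}
        except Exception as exc:  # record and continue
            log.error("stage %s failed: %s", stage, exc)
            report["stages"][stage] = {"status": "failed", "error": str(exc)}

    report["key_outputs"] = _key_outputs(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report


def _key_outputs(report: dict) -> dict:
    out = {}
    stages = report["stages"]
    if stages.get("fickian", {}).get("status") == "ok":
        out["d_w_org"] = stages["fickian"]["d_w_org"]
    if stages.get("se", {}).get("status") == "ok":
        out["alpha"] = stages["se"]["alpha"]
    if stages.get("hop", {}).get("status") == "ok":
        out["timescales_ns"] = stages["hop"]["timescales_ns"]
        out["barrier_mean_kbt"] = stages["hop"]["barrier_mean_kbt"]
    if stages.get("fv", {}).get("status") == "ok":
        out["occupied_fraction"] = stages["fv"]["occupied"]
    return out


def _stage_synth(config: PipelineConfig, seed: int, outdir: Path, art: dict) -> dict:
    p = {**_SYNTH_DEFAULTS, **config.synth}
    truth = DiffusivityParameterization(np.asarray(p["truth_coefficients"]))
    activity = ActivityModel()
    curves = []
    for k, (rh_i, rh_f) in enumerate(p["rh_steps"]):
        rf = gen_response_curve(
            truth,
            (rh_i, rh_f),
            initial_radius=p["initial_radius"],
            activity=activity,
            noise_sd=p["noise_sd"],
            n_points=p["n_points"],
            n_shells=p["n_shells"],
            seed=seed + k,
        )
        io.write_response(rf, outdir / f"response_{k}.csv")
        curves.append(rf)
    jump = dict(p["jump"])
    traj, states = gen_two_state_jump(seed=seed, **jump)
    traj.meta["states"] = states
    io.write_trajectory(traj, outdir / "trajectory.csv", fmt="csv")
    packing = gen_sphere_packing(seed=seed, mode="poisson", **p["packing"])
    io.write_packing(packing, outdir / "packing.csv")
    art["curves"] = curves
    art["activity"] = activity
    art["truth"] = truth
    art["trajectory"] = traj
    art["packing"] = packing
    return {
        "n_curves": len(curves),
        "truth_coefficients": truth.coefficients.tolist(),
        "trajectory_frames": traj.n_frames,
        "packing_spheres": packing.n_spheres,
    }


def _stage_fickian(config: PipelineConfig, seed: int, outdir: Path, art: dict) -> dict:
    if "curves" not in art:
        raise RuntimeError("fickian stage needs the synth stage's curves")
    p = {"order": 2, "n_shells": 40, **config.fickian}
    kww = []
    for rf in art["curves"]:
        fit = fit_kww(rf)
        kww.append({"tau_s": fit.tau, "beta": fit.beta, "rms": fit.residual_rms})
    param, _ = fit_diffusivity(
        art["curves"],
        art["activity"],
        order=p["order"],
        n_shells=p["n_shells"],
        seed=seed,
    )
    io.write_diffusivity(param, outdir / "diffusivity.json")
    art["d_param"] = param
    return {
        "kww": kww,
        "coefficients": param.coefficients.tolist(),
        "d_w_org": param.d_w_org,
    }


def _stage_se(config: PipelineConfig, seed: int, outdir: Path, art: dict) -> dict:
    if "d_param" not in art:
        raise RuntimeError("se stage needs the fickian stage's D(a_w)")
    p = {
        "eta_coefficients": [9.0, -14.0, 2.0],
        "a_w_grid": np.linspace(0.1, 0.7, 13).tolist(),
        **config.se,
    }
    eta_param = ViscosityParameterization(np.asarray(p["eta_coefficients"]))
    table = build_table(art["d_param"], eta_param, np.asarray(p["a_w_grid"]))
    fit = fit_fractional_exponent(table, seed=seed)
    div = divergence_orders(table.d, se_predict(table.eta))
    with open(outdir / "se_table.csv", "w") as fh:
        fh.write(f"# cavitydiff {__version__} se_table\n")
        fh.write("a_w,D_m2s,eta_Pas,divergence_orders,valid\n")
        for k in range(len(table)):
            fh.write(
                f"{table.a_w[k]:.4f},{table.d[k]:.6e},{table.eta[k]:.6e},"
                f"{div[k]:.3f},{int(table.valid[k])}\n"
            )
    return {
        "alpha": fit.alpha,
        "alpha_sd": fit.alpha_sd,
        "max_divergence_orders": float(div.max()),
    }


def _stage_hop(config: PipelineConfig, seed: int, outdir: Path, art: dict) -> dict:
    if "trajectory" not in art:
        raise RuntimeError("hop stage needs the synth stage's trajectory")
    p = {"lag_ps": 10.0, "candidates": [1, 2, 3], "n_bootstrap": 10, **config.hop}
    traj = art["trajectory"]
    msd = msd_diffusion(traj)
    n, diag = select_n_states(
        traj, lag=p["lag_ps"], candidates=p["candidates"], seed=seed
    )
    model = fit_hmm(
        traj, n_states=n, lag=p["lag_ps"], n_bootstrap=p["n_bootstrap"], seed=seed
    )
    stats = hop_statistics(model)
    barriers = []
    for i in range(model.n_states):
        t_ii = model.transmat[i, i]
        if t_ii >= 1.0:
            continue
        escape_rate = -np.log(t_ii) / (model.lag_ps * 1e-3)  # ns^-1
        barriers.append(tst_barrier(escape_rate).delta_g)
    (outdir / "markov_model.json").write_text(json.dumps(model.to_dict(), indent=1))
    return {
        "msd_d_m2s": msd.d,
        "n_states": model.n_states,
        "selection_scores": {str(k): v for k, v in diag["scores"].items()},
        "timescales_ns": model.timescales_ns.tolist(),
        "hops_per_ns": stats.hops_per_ns,
        "return_trip_fraction": stats.return_trip_fraction,
        "barrier_mean_kbt": float(np.mean(barriers)) if barriers else None,
        "barrier_sd_kbt": float(np.std(barriers, ddof=1))
        if len(barriers) > 1
        else None,
    }


def _stage_fv(config: PipelineConfig, seed: int, outdir: Path, art: dict) -> dict:
    if "packing" not in art:
        raise RuntimeError("fv stage needs the synth stage's packing")
    p = {"spacing": 0.05, "probe_radius": 0.0, **config.fv}
    result = occupied_fraction(
        art["packing"], spacing=p["spacing"], probe_radius=p["probe_radius"]
    )
    return {
        "occupied": result.occupied,
        "free": result.free,
        "grid": list(result.n_grid),
    }


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "fickian": _stage_fickian,
    "se": _stage_se,
    "hop": _stage_hop,
    "fv": _stage_fv,
}
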