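"""End-to-end pipeline: counts -> parameters -> cube -> simulation -> metrics.

``run_pipeline`` binds the stages together for one drive line: estimate
cutting/homing/resistance rates per parent sex from a pooled-count CSV,
take the maternal-deposition rate from a trans-heterozygous assay CSV (or a
direct override), derive lifecycle quantities from a fitness CSV, build the
inheritance cube, calibrate the demographic equilibrium, simulate the
release scenario, and write a reproducible artifact bundle (params JSON,
cube CSV, trajectories CSV, metrics JSON, log).  Every derived parameter's
provenance — the input cells or the override that produced it — is recorded
in the run log.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import datasets
from .cube import DriveParams, build_cube
from .estimate import (
    EstimationError,
    TransHetAssay,
    TransHetReplicate,
    derive_lifecycle,
    estimate_cut_params,
    estimate_deposition,
    pooled_counts_from_table,
)
from .popsim import (
    LifecycleParams,
    ReleaseSchedule,
    calibrate_equilibrium,
    scenario_substitute,
    simulate,
    summary_metrics,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "read_transhet_csv"]


class ConfigError(ValueError):
    """Invalid run configuration or malformed input table."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see module docstring)."""

    line: str
    outdir: str
    pools_csv: str | None = None          # defaults to the bundled pool table
    transhet_csv: str | None = None
    fitness_csv: str | None = None        # defaults to the bundled fitness table
    reference_line: str = "HWE"
    dF: float | None = None               # direct override for deposition rate
    estimator: str = "table"
    overrides: dict = field(default_factory=dict)
    seed: int = 0
    reps: int = 1
    days: int = 365
    mode: str = "deterministic"
    release_day: int = 25
    release_count: int = 2000

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            with open(path) as fh:
                raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "line" not in raw or "outdir" not in raw:
            raise ConfigError(f"{path}: config requires 'line' and 'outdir'")
        return cls(**raw)


def read_transhet_csv(path, line: str) -> TransHetAssay:
    """Read a trans-heterozygous assay CSV.

    Expected columns: line, rep, marker_class, n_larvae, n_active_carb109,
    n_active_timp4.
    """
    df = pd.read_csv(path)
    required = ["line", "marker_class", "n_larvae", "n_active_carb109"]
    for col in required:
        if col not in df.columns:
            raise ConfigError(f"{path}: missing column {col!r}")
    sub = df[df["line"] == line]
    if sub.empty:
        raise ConfigError(f"{path}: no rows for line {line!r}")
    reps = []
    for i, row in sub.reset_index(drop=True).iterrows():
        try:
            reps.append(
                TransHetReplicate(
                    marker_class=str(row["marker_class"]),
                    n_larvae=int(row["n_larvae"]),
                    n_active_carb109=int(row["n_active_carb109"]),
                    n_active_timp4=int(row.get("n_active_timp4", 0)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"{path}: row {i}: {exc}") from exc
    return TransHetAssay(line=line, replicates=tuple(reps))


def _load_pool_table(config: RunConfig) -> pd.DataFrame:
    if config.pools_csv is None:
        return datasets.load_ox1_pool_counts()
    try:
        df = pd.read_csv(config.pools_csv)
    except OSError as exc:
        raise ConfigError(f"cannot read pools CSV {config.pools_csv}: {exc}") from exc
    for i, col in enumerate(("line", "parent_sex", "pool", "n_assessed",
                             "gdbi_tested", "gdbi_positive")):
        if col not in df.columns:
            raise ConfigError(
                f"parse error in {config.pools_csv}: missing column {col!r}"
            )
    return df


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run the full pipeline; returns a mapping of artifact names to paths.

    Deterministic given the config seed: rerunning an identical config
    yields byte-identical params JSON and trajectory CSV.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gdsim")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict[str, str]:
    pools_src = config.pools_csv or "bundled OX-1 pool table"
    table = _load_pool_table(config)

    estimates = {}
    for sex in ("F", "M"):
        try:
            counts = pooled_counts_from_table(table, config.line, sex)
        except EstimationError as exc:
            raise ConfigError(f"estimation stage: {exc}") from exc
        est = estimate_cut_params(counts, method=config.estimator)
        estimates[sex] = est
        logger.info(
            "provenance c%s=%.6f ch%s=%.6f cr%s=%.6f from %s line=%s sex=%s "
            "(P=%d, G=%.3f, N=%d, method=%s)",
            sex, est.c, sex, est.ch, sex, est.cr, pools_src, config.line, sex,
            est.n_marker_positive, est.gdbi_estimate, est.n_total, est.method,
        )

    if config.dF is not None:
        d_f = config.dF
        logger.info("provenance dF=%.6f from config override", d_f)
    elif config.transhet_csv is not None:
        assay = read_transhet_csv(config.transhet_csv, config.line)
        d_f = estimate_deposition(assay).dF
        logger.info("provenance dF=%.6f estimated from %s", d_f, config.transhet_csv)
    elif config.line in datasets.CARB109_DEPOSITION_RATE:
        d_f = datasets.CARB109_DEPOSITION_RATE[config.line]
        logger.info("provenance dF=%.6f from bundled drive-locus activity rates", d_f)
    else:
        raise ConfigError(f"no deposition rate available for line {config.line!r}")

    fitness = (
        pd.read_csv(config.fitness_csv) if config.fitness_csv else datasets.load_fitness_defaults()
    )
    try:
        life = derive_lifecycle(fitness, config.line, config.reference_line)
    except (EstimationError, KeyError) as exc:
        raise ConfigError(f"lifecycle stage: {exc}") from exc
    logger.info(
        "provenance betaK=%.4f tLarva=%d xi=%.3f fertility_mult=%.2f from %s "
        "(reference=%s)",
        life["betaK"], life["tLarva"], life["xiF"], life["fertility_mult"],
        config.fitness_csv or "bundled fitness defaults", config.reference_line,
    )

    drive = DriveParams(
        cF=estimates["F"].c, chF=estimates["F"].ch, crF=estimates["F"].cr,
        cM=estimates["M"].c, chM=estimates["M"].ch, crM=estimates["M"].cr,
        dF=d_f, dhF=0.0, drF=1.0,
        fertility_mult=life["fertility_mult"], xiF=life["xiF"], xiM=life["xiM"],
    )
    lifecycle = LifecycleParams(tLarva=life["tLarva"], betaK=life["betaK"])
    scenario = {"drive": drive, "lifecycle": lifecycle}
    if config.overrides:
        scenario = scenario_substitute(scenario, config.overrides)
        drive, lifecycle = scenario["drive"], scenario["lifecycle"]

    cube = build_cube(drive)
    cube_path = outdir / "cube.csv"
    cube.to_csv(str(cube_path))

    params_path = outdir / "params.json"
    payload = {
        "line": config.line,
        "drive": dataclasses.asdict(drive),
        "lifecycle": dataclasses.asdict(lifecycle),
        "seed": config.seed,
        "estimator": config.estimator,
    }
    params_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    cal = calibrate_equilibrium(lifecycle)
    logger.info("calibration gamma=%.6g s0=%.6f f*=%.6f", cal.gamma, cal.s0, cal.f_star)
    rel = ReleaseSchedule.single_male_release(
        day=config.release_day, count=config.release_count
    )
    trajs = simulate(
        cube, lifecycle, rel, drive,
        days=config.days, reps=config.reps, seed=config.seed, mode=config.mode,
        calibration=cal,
    )

    traj_path = outdir / "trajectories.csv"
    pd.concat([t.to_dataframe() for t in trajs], ignore_index=True).to_csv(
        traj_path, index=False, float_format="%.6f"
    )
    metrics_path = outdir / "metrics.json"
    metrics_path.write_text(
        json.dumps(summary_metrics(trajs), indent=2, sort_keys=True) + "\n"
    )
    return {
        "params": str(params_path),
        "cube": str(cube_path),
        "trajectories": str(traj_path),
        "metrics": str(metrics_path),
        "log": str(outdir / "run.log"),
    }
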