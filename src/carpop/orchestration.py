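"""Configuration, logging, seed fan-out and the end-to-end pipeline CLI.

The pipeline chains generate -> fit -> vpop -> classify (sensitivity is
available as its own subcommand; it is the most expensive stage and is not in
the default chain). A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` spawning, so stages are individually
reproducible without seed collisions. Every run writes a provenance record
(config hash, master seed, package version) and a manifest of produced files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import sys
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import fitting, population, response_criteria, sensitivity
from .model_core import PatientParameters, simulate
from .synthetic_data import (CohortDataset, ObservationSchedule,
                             default_patient, default_truth_population,
                             generate_cohort, zero_noise)

logger = logging.getLogger("carpop")

_STAGES = ("generate", "fit", "vpop", "sensitivity", "classify")

DEFAULTS: Dict[str, object] = {
    "seed": 0,
    "out_dir": "carpop_out",
    "stages": ["generate", "fit", "vpop", "classify"],
    "generate": {
        "n_patients": 8,
        "noise": True,
        "responder_effect": None,
        "horizon": 30.0,
    },
    "fit": {
        "layers": [1, 2, 3, 4, 5],
        "n_restarts": 1,
        "max_patients": None,
    },
    "vpop": {
        "n": 100,
        "model_id": 5,
        "alteration": None,  # {"parameter": ..., "mode": ..., "factor": ...}
    },
    "sensitivity": {
        "methods": ["local"],
        "samples_per_param": 200,
        "n_trees": 100,
        "parameters": None,   # optional subset of parameter names
    },
}

_ALTERATION_KEYS = {"parameter": str, "mode": str, "factor": (int, float)}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    data: Dict[str, object]

    def __getitem__(self, key):
        return self.data[key]

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed by SeedSequence spawn."""
        idx = _STAGES.index(stage)
        child = np.random.SeedSequence(self.data["seed"]).spawn(len(_STAGES))[idx]
        return int(child.generate_state(1)[0] % 2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.data, sort_keys=True).encode()).hexdigest()[:16]


def _merge_validate(raw: Dict, defaults: Dict, path: str = "") -> Dict:
    out = {}
    for key, default in defaults.items():
        here = f"{path}{key}"
        if key not in raw:
            out[key] = default
            continue
        v = raw[key]
        if isinstance(default, dict):
            if not isinstance(v, dict):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _merge_validate(v, default, here + ".")
        else:
            out[key] = v
    for key in raw:
        if key not in defaults:
            raise ConfigError(f"{path}{key}: unknown key")
    return out


def validate_config(raw_text: str) -> RunConfig:
    """Parse and validate a YAML config, filling defaults.

    Unknown keys are rejected with their key path; cross-field constraints
    (positive cohort sizes, known stages, well-formed alteration blocks) are
    enforced before any stage runs.
    """
    raw = yaml.safe_load(raw_text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    data = _merge_validate(raw, DEFAULTS)

    if not isinstance(data["seed"], int) or data["seed"] < 0:
        raise ConfigError("seed: must be a non-negative integer")
    for stage in data["stages"]:
        if stage not in _STAGES:
            raise ConfigError(f"stages: unknown stage {stage!r}")
    if data["generate"]["n_patients"] < 1:
        raise ConfigError("generate.n_patients: must be >= 1")
    if data["vpop"]["n"] < 1:
        raise ConfigError("vpop.n: must be >= 1")
    alt = data["vpop"]["alteration"]
    if alt is not None:
        if not isinstance(alt, dict) or set(alt) != set(_ALTERATION_KEYS):
            raise ConfigError("vpop.alteration: needs exactly the keys "
                              "parameter/mode/factor")
        if alt["mode"] not in ("multiply", "add"):
            raise ConfigError("vpop.alteration.mode: must be multiply or add")
    return RunConfig(data=data)


def config_roundtrip(cfg: RunConfig) -> RunConfig:
    """Serialize and re-parse a config (identity by construction)."""
    return validate_config(yaml.safe_dump(cfg.data))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> Dict[str, object]:
    """Execute the configured stages in order; return the manifest.

    Each stage's outputs are the next stage's inputs. A stage failure aborts
    downstream stages and the manifest marks partial completion.
    """
    out_dir = pathlib.Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg["seed"],
        "stages_completed": [],
        "files": [],
        "partial": False,
    }

    def record(paths):
        manifest["files"].extend(str(p) for p in paths)

    dataset: Optional[CohortDataset] = None
    fits: List[fitting.FitResult] = []
    pop_model = None

    try:
        for stage in cfg["stages"]:
            logger.info("stage %s starting", stage)
            seed = cfg.stage_seed(stage)

            if stage == "generate":
                g = cfg["generate"]
                truth = default_truth_population()
                if not g["noise"]:
                    truth = zero_noise(truth)
                dataset = generate_cohort(
                    truth_pop=truth, n_patients=g["n_patients"], seed=seed,
                    responder_effect=g["responder_effect"],
                    horizon=g["horizon"])
                record(dataset.write(out_dir / "dataset"))

            elif stage == "fit":
                if dataset is None:
                    dataset = CohortDataset.read(out_dir / "dataset")
                f = cfg["fit"]
                pids = dataset.patient_ids()
                if f["max_patients"]:
                    pids = pids[: f["max_patients"]]
                init = default_patient()
                rows = []
                for pid in pids:
                    fr = fitting.fit_sequential(
                        dataset.patient_observations(pid), init,
                        layers=f["layers"], n_restarts=f["n_restarts"],
                        seed=seed)
                    fits.append(fr)
                    for name, v in fr.params.to_flat().items():
                        rows.append((pid, name, v))
                path = out_dir / "individual_fits.csv"
                pd.DataFrame(rows, columns=["patient_id", "parameter", "value"]
                             ).to_csv(path, index=False, float_format="%.17g")
                record([path])
                if len(fits) >= 2:
                    pop_model = fitting.fit_population(fits)
                    path = out_dir / "population_fit.csv"
                    pop_model.to_frame().to_csv(path, index=False,
                                                float_format="%.17g")
                    record([path])

            elif stage == "vpop":
                v = cfg["vpop"]
                pop = pop_model or (dataset.truth_pop if dataset else None) \
                    or default_truth_population()
                vp = population.draw_vpop(pop, v["n"], seed, default_patient())
                if v["alteration"]:
                    a = v["alteration"]
                    vp = population.alter_parameters(
                        vp, a["parameter"], a["factor"], a["mode"])
                t_grid = np.linspace(0.0, 30.0, 31)
                bands, failures = population.vpop_outputs(
                    vp, v["model_id"], t_grid)
                frames = [b.to_frame(obs) for obs, b in bands.items()]
                path = out_dir / "vpop_bands.csv"
                pd.concat(frames).to_csv(path, index=False)
                record([path])
                if failures:
                    logger.warning("%d virtual patients failed", len(failures))

            elif stage == "sensitivity":
                s = cfg["sensitivity"]
                pop = pop_model or default_truth_population()
                bounds = sensitivity.bounds_from_population(pop)
                if s["parameters"]:
                    bounds = {k: v for k, v in bounds.items()
                              if k in set(s["parameters"])}
                results = []
                t_grid = np.linspace(0.0, 30.0, 31)
                base = default_patient()
                if "efast" in s["methods"]:
                    design = sensitivity.efast_design(
                        bounds, s["samples_per_param"], resamplings=1,
                        seed=seed)
                    outs = sensitivity.evaluate_outputs(
                        design.X, design.names, base, t_grid)
                    si_rows, tsi_rows = {}, {}
                    for out_name in outs.columns:
                        si, tsi = sensitivity.efast_indices(
                            design, outs[out_name].to_numpy())
                        si_rows[out_name] = si
                        tsi_rows[out_name] = tsi
                    for meth, rows in (("eFAST-SI", si_rows),
                                       ("eFAST-TSI", tsi_rows)):
                        M = pd.DataFrame(rows, index=design.names).T
                        results.append(sensitivity.SensitivityResult(
                            meth, M, has_dummy=True))
                if "local" in s["methods"]:
                    optima = [f.params for f in fits] or [base]
                    names = [n for n in bounds]
                    M = sensitivity.local_sensitivity(
                        optima, sensitivity.model_output_fn(t_grid), names)
                    results.append(sensitivity.SensitivityResult("local", M))
                tidy = pd.concat([r.to_tidy() for r in results])
                norm = pd.concat([r.to_tidy() for r in
                                  sensitivity.normalize_heatmap(results)])
                tidy = tidy.rename(columns={"value": "raw_value"})
                tidy = tidy.merge(
                    norm.rename(columns={"value": "normalized_value"}),
                    on=["method", "output", "parameter"], how="left")
                path = out_dir / "sensitivity.csv"
                tidy.to_csv(path, index=False)
                record([path])
                dummy = tidy[tidy.parameter == sensitivity.DUMMY_NAME]
                if len(dummy):
                    dpath = out_dir / "dummy_report.csv"
                    dummy[["method", "output", "raw_value"]].to_csv(
                        dpath, index=False)
                    record([dpath])

            elif stage == "classify":
                if dataset is None:
                    dataset = CohortDataset.read(out_dir / "dataset")
                rows = []
                for pid, sub in dataset.lesions.groupby("patient_id"):
                    recs = [response_criteria.LesionRecord(
                        r.baseline_d, min(r.baseline_d, r.final_d), r.final_d)
                        for r in sub.itertuples()]
                    h = response_criteria.LesionHistory(
                        baseline_spd=float(sum(r.baseline_d**2
                                               for r in sub.itertuples())),
                        current_spd=float(sum(r.final_d**2
                                              for r in sub.itertuples())),
                        lesions=recs)
                    rows.append((pid, response_criteria.classify(h).value))
                path = out_dir / "responses.csv"
                pd.DataFrame(rows, columns=["patient_id", "response"]
                             ).to_csv(path, index=False)
                record([path])

            manifest["stages_completed"].append(stage)
    except Exception as e:
        logger.error("pipeline aborted at stage failure: %s", e)
        manifest["partial"] = True
        manifest["error"] = str(e)

    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    manifest["files"].append(str(path))
    return manifest


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _load_config(config_path: Optional[str], seed: Optional[int],
                 out: Optional[str]) -> RunConfig:
    text = pathlib.Path(config_path).read_text() if config_path else ""
    cfg = validate_config(text)
    if seed is not None:
        cfg.data["seed"] = seed
    if out is not None:
        cfg.data["out_dir"] = out
    return cfg


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="debug logging to stderr")
def main(verbose):
    """Population mechanistic modelling of month-one CAR T-cell dynamics."""
    logging.basicConfig(stream=sys.stderr,
                        level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
def generate(config_path, seed, out):
    """Generate a synthetic cohort dataset."""
    cfg = _load_config(config_path, seed, out)
    cfg.data["stages"] = ["generate"]
    run_pipeline(cfg)


@main.command(name="simulate")
@click.option("--params", "params_path", type=click.Path(exists=True),
              required=True, help="flat key,value CSV of patient parameters")
@click.option("--model", "model_id", type=click.IntRange(1, 5), default=5)
@click.option("--days", type=float, default=30.0)
@click.option("--out", type=click.Path(), required=True)
def simulate_cmd(params_path, model_id, days, out):
    """Simulate one patient and write the tidy trajectory CSV."""
    df = pd.read_csv(params_path)
    flat = dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))
    pp = PatientParameters.from_flat(flat)
    traj = simulate(model_id, pp, np.linspace(0.0, days, int(days) + 1))
    traj.write_csv(out)


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
def fit(config_path, seed, out):
    """Fit the model hierarchy to a generated dataset."""
    cfg = _load_config(config_path, seed, out)
    cfg.data["stages"] = ["fit"]
    run_pipeline(cfg)


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
def vpop(config_path, seed, out):
    """Draw a virtual population and write quartile bands."""
    cfg = _load_config(config_path, seed, out)
    cfg.data["stages"] = ["vpop"]
    run_pipeline(cfg)


@main.command(name="sensitivity")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
def sensitivity_cmd(config_path, seed, out):
    """Run the configured sensitivity methods."""
    cfg = _load_config(config_path, seed, out)
    cfg.data["stages"] = ["sensitivity"]
    run_pipeline(cfg)


@main.command()
@click.option("--in", "in_path", type=click.Path(exists=True), required=True,
              help="lesion-history CSV: patient_id, lesion_id, baseline_d, "
                   "nadir_d, current_d, new_lesion")
@click.option("--out", type=click.Path(), required=True)
def classify(in_path, out):
    """Classify patients with the simplified Lugano criteria."""
    df = pd.read_csv(in_path)
    rows = []
    for pid, sub in df.groupby("patient_id"):
        recs = [response_criteria.LesionRecord(r.baseline_d, r.nadir_d,
                                               r.current_d)
                for r in sub.itertuples()]
        h = response_criteria.LesionHistory(
            baseline_spd=float((sub.baseline_d**2).sum()),
            current_spd=float((sub.current_d**2).sum()),
            lesions=recs,
            new_lesion=bool(sub.new_lesion.any()))
        rows.append((pid, response_criteria.classify(h).value))
    pd.DataFrame(rows, columns=["patient_id", "response"]
                 ).to_csv(out, index=False)


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), default=None)
def pipeline(config_path, seed, out):
    """Run the full configured stage chain."""
    cfg = _load_config(config_path, seed, out)
    manifest = run_pipeline(cfg)
    click.echo(json.dumps(manifest, indent=2))
    if manifest["partial"]:
        raise SystemExit(1)
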