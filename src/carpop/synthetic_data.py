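"""Synthetic trial-like cohorts with known ground truth.

The clinical tables this package analyses (longitudinal blood counts, flow
phenotype proportions, sparse lesion imaging, LDH and cytokine series) come
from a proprietary trial, so every pipeline stage is exercised instead on
cohorts generated here: per-patient parameters are drawn from a truth
population model, the full model (layer 5) is simulated, and observations are
sampled on a trial-like visit schedule with the population's observation-error
models. Deliberate artefacts of the real data streams are emulated:

* lesion SPD is emitted only at the first and last imaging visit;
* blood CD19+ counts are pinned constant at the limit of quantitation;
* LDH is an affine function of lesion volume plus noise (tumour-burden
  surrogate);
* IL-7 / IL-15 are generated as a*exp(-gamma_i t) + b plus noise with the
  patient's own proliferation-decay rate gamma_i, so the correlation between
  cytokines and the endogenous proliferation rate exists by construction;
* uniform missingness can be layered on with :func:`degrade`.

Defaults: 64 patients, a 30-day horizon, blood sampling on days
0/1/3/5/7/10/14/21/28, weekly phenotyping, imaging on days 0 and 28, and
twice-weekly LDH. The default truth population describes a lymphodepleted
large-B-cell-lymphoma cohort receiving an anti-CD19 product: strong but
decaying homeostatic proliferation (rho0 ~ 0.9/day, gamma ~ 0.12/day),
antigen-driven proliferation about half as fast at full stimulation
(rho_a ~ 0.5/day), ~10 cm^3 lesions, and CAR doses of ~2e6 cells in blood.
"""

from __future__ import annotations

import pathlib
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model_core import PHENOTYPES, PatientParameters, simulate
from .population import (ErrorModel, ParamDistribution, PopulationModel,
                         draw_vpop)

_LOGIT_EPS = 1e-6

#: LDH surrogate model: LDH(t) = LDH_BASE + LDH_PER_CM3 * V(t) + noise (a.u.)
LDH_BASE = 200.0
LDH_PER_CM3 = 10.0

#: normalized cytokine series: a * exp(-gamma_i * t) + b
CYTOKINE_SHAPE = {"IL7": (0.9, 0.1), "IL15": (0.95, 0.05)}


@dataclass
class ObservationSchedule:
    """Visit days for each data stream (days post-infusion, within [0, 30])."""

    blood_days: Sequence[float] = (0, 1, 3, 5, 7, 10, 14, 21, 28)
    phenotype_days: Sequence[float] = (0, 7, 14, 21, 28)
    spd_days: Sequence[float] = (0, 28)
    ldh_days: Sequence[float] = (0, 3, 7, 10, 14, 17, 21, 24, 28)
    cytokine_days: Sequence[float] = (0, 1, 3, 5, 7, 10, 14, 21, 28)

    def all_days(self) -> np.ndarray:
        return np.unique(np.concatenate([
            np.asarray(d, dtype=float) for d in
            (self.blood_days, self.phenotype_days, self.spd_days,
             self.ldh_days, self.cytokine_days)]))

    def validate(self, horizon: float = 30.0) -> None:
        days = self.all_days()
        if days.min() < 0 or days.max() > horizon:
            raise ValueError(f"schedule days must lie within [0, {horizon}]")
        if len(self.spd_days) < 2:
            raise ValueError("need at least baseline and final imaging visits")


def default_patient() -> PatientParameters:
    """Typical post-lymphodepletion patient (the truth-population centre)."""
    return PatientParameters(
        rho0=0.9, gamma=0.12, delta=0.2,
        rho_a=0.5, K_half=2e9, g_tumour=0.02,
        kappa_p=np.array([0.0, 0.0, 1e-8, 1e-8]),
        phi=0.25,
        alpha_1=0.05, alpha_2=0.08, alpha_3=0.05,
        E0=1e8, C0=2e6, B0=1e10,
        pi_endo0=np.array([0.2, 0.35, 0.3, 0.15]),
        pi_car0=np.array([0.05, 0.45, 0.35, 0.15]),
        B_blood_loq=1e5, v_cell=1e-9,
    )


def default_truth_population() -> PopulationModel:
    """Truth population the default synthetic cohorts are drawn from.

    Locations sit at the default patient's values; lognormal spreads of
    0.15-0.5 on the log scale give the order-of-magnitude inter-patient
    variability seen in CAR T-cell expansion, the death rate is Gaussian,
    initial phenotype proportions are logit-normal. The lesion:blood
    partition ratio phi is held fixed across the cohort (it is structurally
    non-identifiable from blood counts and SPD, so fits keep it frozen).
    """
    base = default_patient()

    def ln(v, s):
        return ParamDistribution("lognormal", float(np.log(v)), s)

    params = {
        "rho0": ln(base.rho0, 0.15),
        "gamma": ln(base.gamma, 0.15),
        "delta": ParamDistribution("normal", base.delta, 0.02),
        "rho_a": ln(base.rho_a, 0.25),
        "K_half": ln(base.K_half, 0.3),
        "g_tumour": ln(base.g_tumour, 0.3),
        "kappa_em": ln(base.kappa_p[2], 0.3),
        "E0": ln(base.E0, 0.4),
        "C0": ln(base.C0, 0.5),
        "B0": ln(base.B0, 0.4),
        "alpha_1": ln(base.alpha_1, 0.2),
        "alpha_2": ln(base.alpha_2, 0.2),
        "alpha_3": ln(base.alpha_3, 0.2),
    }
    for vec, name in ((base.pi_endo0, "pi_endo0"), (base.pi_car0, "pi_car0")):
        for i, p in enumerate(PHENOTYPES):
            params[f"{name}_{p}"] = ParamDistribution(
                "logitnormal", float(logit(vec[i])), 0.3)

    error_models = {
        "E_blood": ErrorModel("proportional", b=0.25),
        "C_blood": ErrorModel("proportional", b=0.25),
        "spd": ErrorModel("proportional", b=0.1),
        "props": ErrorModel("additive", a=0.2),   # applied on the logit scale
        "LDH": ErrorModel("additive", a=10.0),
        "IL7": ErrorModel("additive", a=0.05),
        "IL15": ErrorModel("additive", a=0.03),
    }
    return PopulationModel(params=params, error_models=error_models)


def zero_noise(pop: PopulationModel) -> PopulationModel:
    """Copy of a population model with all observation noise switched off."""
    return PopulationModel(
        params=dict(pop.params), correlation=pop.correlation,
        error_models={k: ErrorModel(e.family, 0.0, 0.0)
                      for k, e in pop.error_models.items()})


@dataclass
class CohortDataset:
    """The four synthetic tables plus the generating truth.

    observations: patient_id, time_day, observable, value, unit
    lesions:      patient_id, lesion_id, baseline_d, final_d
    covariates:   patient_id, time_day, covariate, value
    truth:        patient_id, parameter, value
    """

    observations: pd.DataFrame
    lesions: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame
    truth_pop: Optional[PopulationModel] = None

    def patient_ids(self) -> List:
        return list(self.observations.patient_id.unique())

    def patient_observations(self, pid) -> pd.DataFrame:
        return self.observations[self.observations.patient_id == pid]

    def truth_params(self, pid) -> PatientParameters:
        sub = self.truth[self.truth.patient_id == pid]
        flat = dict(zip(sub.parameter, sub.value))
        return PatientParameters.from_flat(flat)

    _TABLES = ("observations", "lesions", "covariates", "truth")

    def write(self, directory) -> List[pathlib.Path]:
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        written = []
        for name in self._TABLES:
            path = d / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False, float_format="%.17g")
            written.append(path)
        if self.truth_pop is not None:
            path = d / "population.csv"
            self.truth_pop.to_frame().to_csv(path, index=False,
                                             float_format="%.17g")
            written.append(path)
        return written

    @classmethod
    def read(cls, directory) -> "CohortDataset":
        d = pathlib.Path(directory)
        tables = {name: pd.read_csv(d / f"{name}.csv",
                                    float_precision="round_trip")
                  for name in cls._TABLES}
        # integer-valued floats (e.g. counts at the LOQ) must stay float
        for name, cols in (("observations", ("time_day", "value")),
                           ("covariates", ("time_day", "value")),
                           ("truth", ("value",)),
                           ("lesions", ("baseline_d", "final_d"))):
            for c in cols:
                tables[name][c] = tables[name][c].astype(float)
        pop = None
        if (d / "population.csv").exists():
            pop = PopulationModel.from_frame(
                pd.read_csv(d / "population.csv",
                            float_precision="round_trip"))
        return cls(truth_pop=pop, **tables)


def _noisy_logit_props(P: np.ndarray, a: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Additive logit-scale noise on a (4, T) proportion block, renormalized."""
    if a == 0:
        return P
    z = logit(np.clip(P, _LOGIT_EPS, 1 - _LOGIT_EPS))
    noisy = expit(z + a * rng.standard_normal(P.shape))
    return noisy / noisy.sum(axis=0, keepdims=True)


def generate_cohort(truth_pop: Optional[PopulationModel] = None,
                    n_patients: int = 64,
                    schedule: Optional[ObservationSchedule] = None,
                    seed: int = 0,
                    base: Optional[PatientParameters] = None,
                    responder_effect: Optional[float] = None,
                    n_lesions: int = 1,
                    horizon: float = 30.0) -> CohortDataset:
    """Generate a fully synthetic cohort with known ground truth.

    Per patient: truth parameters are drawn from ``truth_pop`` (the effector
    and effector-memory killing constants are tied, matching the model's
    effector-weighted killing design), model 5 is simulated, and observations
    are sampled at the scheduled visits through the population's error
    models. ``responder_effect`` multiplies rho_a for the first half of the
    cohort, creating a built-in good/poor responder contrast. Identical seeds
    give bitwise-identical datasets.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    truth_pop = truth_pop or default_truth_population()
    schedule = schedule or ObservationSchedule()
    schedule.validate(horizon)
    base = base or default_patient()

    ss = np.random.SeedSequence(seed)
    draw_seed, noise_seed = (int(s.generate_state(1)[0] % 2**31)
                             for s in ss.spawn(2))
    vpop = draw_vpop(truth_pop, n_patients, draw_seed, base)
    # tie the effector-memory and terminal-effector killing constants
    vpop = [pp.replace(kappa_p=np.array(
        [0.0, 0.0, pp.kappa_p[2], pp.kappa_p[2]])) for pp in vpop]
    if responder_effect is not None:
        half = n_patients // 2
        vpop = [pp.replace(rho_a=pp.rho_a * responder_effect) if i < half
                else pp for i, pp in enumerate(vpop)]

    rng = np.random.default_rng(noise_seed)
    err = truth_pop.error_models
    t_grid = np.union1d(np.linspace(0.0, horizon, int(horizon) * 4 + 1),
                        schedule.all_days())

    obs_rows, cov_rows, truth_rows, lesion_rows = [], [], [], []
    for i, pp in enumerate(vpop):
        pid = f"P{i:03d}"
        traj = simulate(5, pp, t_grid, n_lesions=n_lesions)

        def at(series, days):
            return np.interp(np.asarray(days, dtype=float), t_grid, series)

        def emit(days, name, values, unit):
            for t, v in zip(days, values):
                obs_rows.append((pid, float(t), name, float(v), unit))

        bd = np.asarray(schedule.blood_days, dtype=float)
        for name, series in (("E_blood", traj.E_b), ("C_blood", traj.C_b)):
            y = at(series, bd)
            if name in err:
                y = err[name].apply(y, rng)
            emit(bd, name, y, "cells/5.3L")
        emit(bd, "cd19_blood", np.full(bd.shape, pp.B_blood_loq), "cells/5.3L")

        phd = np.asarray(schedule.phenotype_days, dtype=float)
        a_prop = err["props"].a if "props" in err else 0.0
        for prefix, block in (("endo_prop", traj.E_b_pheno /
                               traj.E_b_pheno.sum(axis=0, keepdims=True)),
                              ("car_prop", traj.C_pheno_prop)):
            P = np.vstack([at(block[j], phd) for j in range(4)])
            P = _noisy_logit_props(P, a_prop, rng)
            for j, ph in enumerate(PHENOTYPES):
                emit(phd, f"{prefix}_{ph}", P[j], "1")

        # imaging only at the first and last scheduled visit (sparse lesions)
        sd = np.asarray([schedule.spd_days[0], schedule.spd_days[-1]],
                        dtype=float)
        y = at(traj.spd, sd)
        if "spd" in err:
            y = err["spd"].apply(y, rng)
        emit(sd, "spd", y, "cm^2")

        ld = np.asarray(schedule.ldh_days, dtype=float)
        ldh = LDH_BASE + LDH_PER_CM3 * at(traj.lesion_volume, ld)
        if "LDH" in err:
            ldh = err["LDH"].apply(ldh, rng)
        for t, v in zip(ld, ldh):
            cov_rows.append((pid, float(t), "LDH", float(v)))

        cd = np.asarray(schedule.cytokine_days, dtype=float)
        for cyt, (a, b) in CYTOKINE_SHAPE.items():
            y = a * np.exp(-pp.gamma * cd) + b
            if cyt in err:
                y = np.clip(err[cyt].apply(y, rng), 0.0, None)
            for t, v in zip(cd, y):
                cov_rows.append((pid, float(t), cyt, float(v)))

        d = traj.lesion_diameter
        for k in range(n_lesions):
            lesion_rows.append((pid, k, float(d[0]), float(d[-1])))

        for name, v in pp.to_flat().items():
            truth_rows.append((pid, name, float(v)))

    return CohortDataset(
        observations=pd.DataFrame(obs_rows, columns=[
            "patient_id", "time_day", "observable", "value", "unit"]),
        lesions=pd.DataFrame(lesion_rows, columns=[
            "patient_id", "lesion_id", "baseline_d", "final_d"]),
        covariates=pd.DataFrame(cov_rows, columns=[
            "patient_id", "time_day", "covariate", "value"]),
        truth=pd.DataFrame(truth_rows, columns=[
            "patient_id", "parameter", "value"]),
        truth_pop=truth_pop,
    )


def degrade(dataset: CohortDataset, missingness_rate: float,
            seed: int = 0) -> CohortDataset:
    """Drop observation rows uniformly at the given rate (baseline kept).

    Emulates the sparser-than-ideal sampling of real trial tables. The
    baseline (day 0) visit is never dropped and the truth table is untouched.
    """
    if not 0 <= missingness_rate < 1:
        raise ValueError("missingness rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    obs = dataset.observations
    drop = (rng.random(len(obs)) < missingness_rate) & (obs.time_day > 0)
    return CohortDataset(
        observations=obs[~drop].reset_index(drop=True),
        lesions=dataset.lesions.copy(),
        covariates=dataset.covariates.copy(),
        truth=dataset.truth.copy(),
        truth_pop=dataset.truth_pop,
    )
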