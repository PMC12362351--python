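"""Virtual-patient populations: distributions, sampling, parameter alteration.

A :class:`PopulationModel` holds, for each patient parameter, a distribution
family (normal, lognormal or logit-normal) with a location and scale defined
on the family's latent Gaussian scale, an optional correlation matrix between
latent variables, and per-observable observation-error models. Virtual
patients are drawn by sampling correlated latent normals, transforming each
coordinate to its natural scale, and renormalizing phenotype-proportion
vectors onto the simplex.

Parameter-alteration experiments multiply (or shift) one named parameter in
every virtual patient and re-simulate; quartile bands over the cohort
summarize the effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model_core import (PHENOTYPES, PatientParameters, SimulationError,
                         simulate)

logger = logging.getLogger(__name__)

FAMILIES = ("normal", "lognormal", "logitnormal")
ERROR_FAMILIES = ("additive", "proportional", "combined")

#: flat parameter names that live on the unit interval (logit-normal families)
PROPORTION_PARAMS = tuple(f"pi_endo0_{p}" for p in PHENOTYPES) + \
    tuple(f"pi_car0_{p}" for p in PHENOTYPES)


@dataclass
class ParamDistribution:
    """One parameter's population distribution on its latent Gaussian scale.

    ``location``/``scale`` are the mean/sd of the latent normal; the natural
    value is the latent for "normal", exp(latent) for "lognormal" and
    expit(latent) for "logitnormal".
    """

    family: str
    location: float
    scale: float

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")

    def transform(self, z):
        x = self.location + self.scale * np.asarray(z, dtype=float)
        if self.family == "lognormal":
            return np.exp(x)
        if self.family == "logitnormal":
            return expit(x)
        return x

    def to_latent(self, value):
        v = np.asarray(value, dtype=float)
        if self.family == "lognormal":
            return np.log(v)
        if self.family == "logitnormal":
            return logit(v)
        return v


@dataclass
class ErrorModel:
    """Observation-noise model for one observable.

    additive:      y = f + a * eps
    proportional:  y = f * exp(b * eps)   (lognormal, keeps counts positive)
    combined:      y = f * exp(b * eps1) + a * eps2
    with eps ~ N(0, 1). For proportion-type observables the additive model is
    applied on the logit scale by the generator.
    """

    family: str
    a: float = 0.0
    b: float = 0.0

    def __post_init__(self):
        if self.family not in ERROR_FAMILIES:
            raise ValueError(f"unknown error family {self.family!r}")
        if self.a < 0 or self.b < 0:
            raise ValueError("error magnitudes must be >= 0")

    def apply(self, f: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        y = f.copy()
        if self.family in ("proportional", "combined") and self.b > 0:
            y = y * np.exp(self.b * rng.standard_normal(f.shape))
        if self.family in ("additive", "combined") and self.a > 0:
            y = y + self.a * rng.standard_normal(f.shape)
        return y


@dataclass
class PopulationModel:
    """Population distributions + optional latent correlations + error models."""

    params: Dict[str, ParamDistribution]
    correlation: Optional[pd.DataFrame] = None  # names x names, latent scale
    error_models: Dict[str, ErrorModel] = field(default_factory=dict)

    def validate(self) -> None:
        for name in PROPORTION_PARAMS:
            if name in self.params and self.params[name].family != "logitnormal":
                raise ValueError(f"proportion parameter {name} must be logit-normal")
        if self.correlation is not None:
            R = self.correlation.to_numpy(dtype=float)
            names = list(self.correlation.index)
            if list(self.correlation.columns) != names:
                raise ValueError("correlation matrix index/columns must match")
            if not set(names) <= set(self.params):
                raise ValueError("correlation names must be population parameters")
            if not np.allclose(R, R.T, atol=1e-12):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-12):
                raise ValueError("correlation matrix must have unit diagonal")
            w = np.linalg.eigvalsh(R)
            if w.min() < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")

    # -- structured-text (CSV) round trip used by the CLI ------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [(k, d.family, d.location, d.scale)
                for k, d in self.params.items()]
        return pd.DataFrame(rows, columns=["parameter", "family",
                                           "location", "scale"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   error_models: Optional[Dict[str, ErrorModel]] = None
                   ) -> "PopulationModel":
        params = {r.parameter: ParamDistribution(r.family, r.location, r.scale)
                  for r in df.itertuples()}
        return cls(params=params, error_models=error_models or {})


@dataclass
class QuartileBands:
    """Per-time-point median, interquartile range and 5-95% band."""

    t: np.ndarray
    q05: np.ndarray
    q25: np.ndarray
    q50: np.ndarray
    q75: np.ndarray
    q95: np.ndarray

    def to_frame(self, observable: str) -> pd.DataFrame:
        return pd.DataFrame({
            "observable": observable, "time_day": self.t,
            "q05": self.q05, "q25": self.q25, "q50": self.q50,
            "q75": self.q75, "q95": self.q95,
        })


def draw_vpop(pop: PopulationModel, n: int, seed: int,
              base: PatientParameters) -> List[PatientParameters]:
    """Draw ``n`` virtual patients from the population model.

    Latent Gaussians are drawn with the given seed (identical seeds give
    bitwise-identical draws), correlated via the Cholesky factor of the
    latent correlation matrix, transformed per family, and written over the
    ``base`` parameter set. Phenotype-proportion vectors are renormalized to
    the simplex after sampling.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    pop.validate()
    rng = np.random.default_rng(seed)
    names = list(pop.params)
    Z = rng.standard_normal((n, len(names)))
    if pop.correlation is not None:
        cn = list(pop.correlation.index)
        R = pop.correlation.to_numpy(dtype=float)
        # eigen-clip for semi-definite matrices that are not strictly PD
        w, V = np.linalg.eigh(R)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        idx = [names.index(c) for c in cn]
        Z[:, idx] = Z[:, idx] @ L.T

    out: List[PatientParameters] = []
    for i in range(n):
        flat = base.to_flat()
        for j, name in enumerate(names):
            flat[name] = float(pop.params[name].transform(Z[i, j]))
        pp = PatientParameters.from_flat(flat, renormalize_props=True)
        pp.validate()
        out.append(pp)
    return out


def alter_parameters(vpop: Sequence[PatientParameters], parameter_name: str,
                     factor: float, mode: str = "multiply"
                     ) -> List[PatientParameters]:
    """Apply ``multiply`` or ``add`` with ``factor`` to one parameter cohort-wide.

    Proportion entries that leave [0, 1] are capped at 1 and the phenotype
    vector renormalized; all other invariants are re-validated.
    """
    if mode not in ("multiply", "add"):
        raise ValueError(f"mode must be 'multiply' or 'add', got {mode!r}")
    if not np.isfinite(factor):
        raise ValueError("factor must be finite")
    sample = vpop[0].to_flat() if vpop else PatientParameters.from_flat
    if vpop and parameter_name not in vpop[0].to_flat():
        raise KeyError(f"unknown parameter {parameter_name!r}")

    out = []
    for pp in vpop:
        flat = pp.to_flat()
        v = flat[parameter_name]
        flat[parameter_name] = v * factor if mode == "multiply" else v + factor
        renorm = parameter_name in PROPORTION_PARAMS
        if renorm:
            flat[parameter_name] = min(max(flat[parameter_name], 0.0), 1.0)
        new = PatientParameters.from_flat(flat, renormalize_props=renorm)
        new.validate()
        out.append(new)
    return out


#: trajectory attributes summarized by default in cohort bands
DEFAULT_OBSERVABLES = ("C_b", "E_b", "spd", "lesion_volume")


def vpop_outputs(vpop: Sequence[PatientParameters], model_id: int,
                 t_grid: Sequence[float],
                 observables: Sequence[str] = DEFAULT_OBSERVABLES,
                 error_models: Optional[Dict[str, ErrorModel]] = None,
                 seed: Optional[int] = None,
                 ) -> Tuple[Dict[str, QuartileBands], List[Tuple[int, str]]]:
    """Simulate every virtual patient and summarize observables as bands.

    Returns (bands per observable, list of (patient index, error message) for
    failed simulations, which are excluded rather than fatal). When
    ``error_models`` is given, observation noise is drawn per patient per
    observable before the quantiles are taken. Quantiles interpolate linearly
    between order statistics.
    """
    if len(vpop) == 0:
        raise ValueError("vpop must be non-empty")
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    series = {obs: [] for obs in observables}
    failures: List[Tuple[int, str]] = []
    for i, pp in enumerate(vpop):
        try:
            traj = simulate(model_id, pp, t_grid)
        except (SimulationError, ValueError) as e:
            failures.append((i, str(e)))
            logger.warning("virtual patient %d failed: %s", i, e)
            continue
        for obs in observables:
            y = getattr(traj, obs)
            if y is None:
                raise ValueError(f"model {model_id} has no observable {obs!r}")
            y = np.asarray(y, dtype=float)
            if error_models and obs in error_models:
                y = error_models[obs].apply(y, rng)
            series[obs].append(y)

    bands = {}
    for obs, rows in series.items():
        A = np.vstack(rows)
        q = np.quantile(A, [0.05, 0.25, 0.5, 0.75, 0.95], axis=0,
                        method="linear")
        bands[obs] = QuartileBands(t=t_grid, q05=q[0], q25=q[1], q50=q[2],
                                   q75=q[3], q95=q[4])
    return bands, failures
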