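"""Five-technique sensitivity suite for the CAR T-cell model outputs.

Quantifies how strongly the summary outputs — Cmax, tmax, AUC of the blood
CAR count, the ordinal-coded simplified Lugano response, and the proportional
tumour-size change — depend on model parameters, using:

* eFAST (extended Fourier Amplitude Sensitivity Test): variance-based global
  first-order (SI) and total (TSI) indices, computed from search curves that
  drive one parameter at a high frequency and the complement at low,
  interference-separated frequencies (Saltelli-style construction with random
  phase resampling). Implemented here directly.
* Random-forest importance indices, trained on either the global sweep
  samples, virtual-patient draws, or per-patient fitted optima; all rows are
  used for training (the forest is never used for prediction).
* Spearman rank correlation between parameters and outputs on virtual
  patients or optima.
* Local sensitivity: each optimum parameter perturbed by +/-1%, mean absolute
  relative output change across patients and directions.

A dummy (deliberately non-influential) parameter rides along in the
stochastic methods; its apparent index estimates the noise floor and is
subtracted off during heatmap normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor

from .model_core import (PatientParameters, SimulationError, derived_outputs,
                         simulate)
from .population import PopulationModel, PROPORTION_PARAMS

logger = logging.getLogger(__name__)

DUMMY_NAME = "dummy"

#: model outputs analysed by every method
OUTPUTS = ("cmax", "tmax", "auc", "luganoResponse", "propTmrSizeChange")


# ---------------------------------------------------------------------------
# eFAST
# ---------------------------------------------------------------------------

@dataclass
class EfastDesign:
    """Search-curve sample matrix plus the metadata the estimator needs.

    Rows are grouped in blocks of ``samples_per_param``: one block per
    (resampling, driver parameter) pair, ordered resampling-major.
    """

    X: np.ndarray                    # (N * D * M_r, D)
    names: List[str]
    samples_per_param: int
    resamplings: int
    interference: int
    omega_max: int

    @property
    def n_params(self) -> int:
        return len(self.names)


def efast_design(bounds: Dict[str, Tuple[float, float]],
                 samples_per_param: int = 1000, resamplings: int = 4,
                 include_dummy: bool = True, seed: int = 0,
                 interference: int = 4) -> EfastDesign:
    """Build the eFAST sample matrix.

    For each of ``resamplings`` random-phase curve sets and each driver
    parameter, ``samples_per_param`` points are taken along a space-filling
    search curve x_k(s) = 0.5 + arcsin(sin(omega_k s + phi_k))/pi, with the
    driver at the maximum frequency omega_max = (N-1)/(2*interference) and the
    complementary parameters at low frequencies <= omega_max/(2*interference).
    A dummy parameter on [0, 1] is appended when requested. The total row
    count is N * D * M_r (D including the dummy).
    """
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names], dtype=float)
    hi = np.array([bounds[k][1] for k in names], dtype=float)
    if np.any(lo >= hi):
        bad = [k for k, a, b in zip(names, lo, hi) if a >= b]
        raise ValueError(f"need lo < hi for parameters {bad}")
    if include_dummy:
        names = names + [DUMMY_NAME]
        lo = np.append(lo, 0.0)
        hi = np.append(hi, 1.0)
    D = len(names)
    N, M = samples_per_param, interference

    omega_max = (N - 1) // (2 * M)
    m = omega_max // (2 * M)
    if m < 1:
        n_min = 8 * M * M + 1
        raise ValueError(
            f"samples_per_param={N} too small for interference factor {M}; "
            f"need at least {n_min} for distinct complementary frequencies")
    if m >= D - 1:
        omega_c = np.floor(np.linspace(1, m, max(D - 1, 1))).astype(int)
    else:
        omega_c = (np.arange(D - 1) % m) + 1

    rng = np.random.default_rng(seed)
    s = 2.0 * np.pi * np.arange(N) / N
    blocks = []
    for _ in range(resamplings):
        for i in range(D):
            omega = np.empty(D, dtype=int)
            omega[i] = omega_max
            omega[np.arange(D) != i] = omega_c
            phase = rng.uniform(0, 2 * np.pi, size=D)
            u = 0.5 + np.arcsin(np.sin(np.outer(s, omega) + phase)) / np.pi
            blocks.append(lo + (hi - lo) * u)
    X = np.vstack(blocks)
    return EfastDesign(X=X, names=names, samples_per_param=N,
                       resamplings=resamplings, interference=M,
                       omega_max=omega_max)


def efast_indices(design: EfastDesign, y: np.ndarray
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """First-order (SI) and total (TSI) indices per parameter from outputs ``y``.

    ``y`` aligns with ``design.X`` rows. Non-finite outputs (failed model
    runs) are imputed by the finite median, provided at least 99% of rows are
    finite. Per block, the variance at the driver frequency's first
    ``interference`` harmonics over the total spectral variance gives SI; one
    minus the low-frequency (complementary) share gives TSI. Indices are
    averaged over the resampling curves.
    """
    y = np.asarray(y, dtype=float).copy()
    if len(y) != len(design.X):
        raise ValueError("y must have one entry per design row")
    bad = ~np.isfinite(y)
    if bad.any():
        frac = bad.mean()
        if frac > 0.01:
            raise ValueError(f"{frac:.1%} of outputs are non-finite (limit 1%)")
        logger.warning("imputing %d non-finite outputs by the median", bad.sum())
        y[bad] = np.median(y[~bad])

    N, D, Mr = design.samples_per_param, design.n_params, design.resamplings
    M, omega = design.interference, design.omega_max
    SI = np.zeros((Mr, D))
    TSI = np.zeros((Mr, D))
    for r in range(Mr):
        for i in range(D):
            blk = y[(r * D + i) * N:(r * D + i + 1) * N]
            F = np.fft.fft(blk - blk.mean())
            # one-sided power spectrum at frequencies 1 .. (N-1)//2
            Sp = (np.abs(F[1:(N + 1) // 2]) ** 2) / N ** 2
            V = 2.0 * Sp.sum()
            if V == 0:
                warnings.warn("constant output: sensitivity indices set to 0")
                continue
            harmonics = omega * np.arange(1, M + 1)
            Vi = 2.0 * Sp[harmonics - 1].sum()
            Vc = 2.0 * Sp[:omega // 2].sum()
            SI[r, i] = Vi / V
            TSI[r, i] = 1.0 - Vc / V
    return SI.mean(axis=0), TSI.mean(axis=0)


# ---------------------------------------------------------------------------
# Random forest / Spearman / local
# ---------------------------------------------------------------------------

def rf_importance(X: np.ndarray, y: np.ndarray, n_trees: int = 100,
                  seed: int = 0) -> np.ndarray:
    """Random-forest importance indices, trained on all rows (no held-out split)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 50:
        raise ValueError("need >= 50 rows to train the forest")
    if np.ptp(y) == 0:
        warnings.warn("constant output: uniform importances returned")
        return np.full(X.shape[1], 1.0 / X.shape[1])
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    rf.fit(X, y)
    return rf.feature_importances_


def spearman_sensitivity(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rank correlation of each parameter column with the output."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 3:
        raise ValueError("need >= 3 rows")
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0 or np.ptp(y) == 0:
            out[j] = 0.0
        else:
            out[j] = spearmanr(X[:, j], y).statistic
    return out


def local_sensitivity(optima: Sequence[PatientParameters],
                      output_fn: Callable[[PatientParameters], Dict[str, float]],
                      param_names: Sequence[str],
                      perturbation: float = 0.01) -> pd.DataFrame:
    """Mean absolute relative output change under +/-1% parameter perturbation.

    For each patient optimum, each parameter is multiplied by (1 + eps) and
    (1 - eps); the score per (output, parameter) is the mean over patients and
    both directions of \\|delta output / output\\|. Patient-output pairs with a
    zero baseline output are skipped (logged).
    """
    sums: Dict[Tuple[str, str], float] = {}
    counts: Dict[Tuple[str, str], int] = {}
    outputs_seen: List[str] = []
    for pp in optima:
        base = output_fn(pp)
        for out_name in base:
            if out_name not in outputs_seen:
                outputs_seen.append(out_name)
        for name in param_names:
            flat = pp.to_flat()
            for sign in (+1.0, -1.0):
                d = dict(flat)
                d[name] = flat[name] * (1.0 + sign * perturbation)
                pert = output_fn(PatientParameters.from_flat(
                    d, renormalize_props=True))
                for out_name, y0 in base.items():
                    if y0 == 0:
                        logger.info("zero baseline %s skipped", out_name)
                        continue
                    key = (out_name, name)
                    sums[key] = sums.get(key, 0.0) + abs(
                        (pert[out_name] - y0) / y0)
                    counts[key] = counts.get(key, 0) + 1
    mat = pd.DataFrame(0.0, index=outputs_seen, columns=list(param_names))
    for (out_name, name), s in sums.items():
        mat.loc[out_name, name] = s / counts[(out_name, name)]
    return mat


# ---------------------------------------------------------------------------
# Results container and heatmap normalization
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """One method's outputs-by-parameters sensitivity matrix.

    ``matrix`` is a DataFrame (rows = outputs, columns = parameters,
    optionally including a ``dummy`` column). ``method`` is one of
    eFAST-SI, eFAST-TSI, RF-global, RF-vpop, RF-optima, SRC-vpop,
    SRC-optima, local.
    """

    method: str
    matrix: pd.DataFrame
    has_dummy: bool = False
    normalized: bool = False

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for out_name in self.matrix.index:
            for par in self.matrix.columns:
                rows.append((self.method, out_name, par,
                             float(self.matrix.loc[out_name, par])))
        return pd.DataFrame(rows, columns=["method", "output", "parameter",
                                           "value"])


def normalize_heatmap(results: Sequence[SensitivityResult]
                      ) -> List[SensitivityResult]:
    """Dummy-subtract (where applicable), floor at 0, scale each row to max 1.

    Absolute values are taken first (Spearman correlations are signed). Rows
    that are zero after dummy subtraction stay zero. The dummy column is
    dropped from the normalized output.
    """
    out = []
    for res in results:
        M = res.matrix.abs().copy()
        if res.has_dummy and DUMMY_NAME in M.columns:
            M = M.sub(M[DUMMY_NAME], axis=0).drop(columns=[DUMMY_NAME])
        M = M.clip(lower=0.0)
        rowmax = M.max(axis=1)
        M = M.div(rowmax.where(rowmax > 0, 1.0), axis=0)
        out.append(SensitivityResult(method=res.method, matrix=M,
                                     has_dummy=False, normalized=True))
    return out


# ---------------------------------------------------------------------------
# Model-facing helpers
# ---------------------------------------------------------------------------

def model_output_fn(t_grid: np.ndarray, model_id: int = 5, n_lesions: int = 1
                    ) -> Callable[[PatientParameters], Dict[str, float]]:
    """Return a params -> {output: value} function over the given time grid."""

    def fn(pp: PatientParameters) -> Dict[str, float]:
        traj = simulate(model_id, pp, t_grid, n_lesions=n_lesions, rtol=1e-8)
        return derived_outputs(traj).to_dict()

    return fn


def evaluate_outputs(X: np.ndarray, names: Sequence[str],
                     base: PatientParameters, t_grid: np.ndarray,
                     model_id: int = 5, max_fail_frac: float = 0.05
                     ) -> pd.DataFrame:
    """Run the model for each sample row; failed rows become NaN.

    Columns not naming a patient parameter (e.g. the dummy) are ignored by
    the model. Aborts if more than ``max_fail_frac`` of rows fail.
    """
    fn = model_output_fn(t_grid, model_id=model_id)
    base_flat = base.to_flat()
    rows = []
    n_fail = 0
    for x in np.asarray(X, dtype=float):
        flat = dict(base_flat)
        for name, v in zip(names, x):
            if name in base_flat:
                flat[name] = float(v)
        try:
            pp = PatientParameters.from_flat(flat, renormalize_props=True)
            pp.validate()
            rows.append(fn(pp))
        except (SimulationError, ValueError) as e:
            n_fail += 1
            rows.append({k: np.nan for k in OUTPUTS})
    if n_fail > max_fail_frac * len(X):
        raise RuntimeError(
            f"{n_fail}/{len(X)} model evaluations failed (limit "
            f"{max_fail_frac:.0%})")
    if n_fail:
        logger.warning("%d/%d model evaluations failed (median-imputed "
                       "downstream)", n_fail, len(X))
    return pd.DataFrame(rows)


def bounds_from_population(pop: PopulationModel, k_sd: float = 3.0,
                           eps: float = 1e-4
                           ) -> Dict[str, Tuple[float, float]]:
    """Global sweep bounds: location +/- k_sd scales on each latent scale.

    The latent interval is transformed to the natural scale per family;
    proportion-type parameters are truncated into (eps, 1-eps). Parameters
    with zero scale are excluded (no range to sweep).
    """
    bounds = {}
    for name, dist in pop.params.items():
        if dist.scale == 0:
            continue
        lo = dist.transform(-k_sd)
        hi = dist.transform(k_sd)
        if dist.family == "logitnormal":
            lo, hi = max(lo, eps), min(hi, 1 - eps)
        bounds[name] = (float(lo), float(hi))
    return bounds
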