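"""Hierarchical ODE models of endogenous and CAR T-cell dynamics over month one.

Five nested model layers describe the first 30 days after anti-CD19 CAR T-cell
infusion in lymphoma patients:

1. endogenous T-cells in blood,
2. endogenous + CAR T-cells in blood,
3. endogenous + CAR T-cells in blood and lesion (with CD19+ target cells),
4. endogenous T-cells and their phenotypes in blood,
5. the full system: endogenous and CAR T-cells, phenotypes, blood and lesion.

Each layer extends the previous ones without changing them: the total
endogenous count is identical across models 1, 2, 4, and the total CAR count
is identical across models 3 and 5 (with the same parameters).

Core mechanisms
---------------
* Antigen-independent ("endogenous-driven") proliferation decays exponentially
  after lymphodepletion: rho_e(t) = rho0 * exp(-gamma * t). It acts on both
  endogenous and CAR T-cells.
* CAR T-cells in the lesion receive additional antigen-driven proliferation
  with saturating (Michaelis) dependence on the CD19+ target count:
  rho_a * B / (B + K_half).
* CAR T-cells partition between blood and lesion at a constant ratio
  C_l = phi * C_b (quasi-equilibrium: extravasation is fast relative to
  proliferation, killing and death).
* Phenotypes (naive -> central memory -> effector memory -> terminal effector)
  differentiate along an irreversible linear chain with rates alpha_1..3;
  proliferation and death are phenotype-uniform, so total counts are
  independent of phenotype composition.
* Lesion CD19+ cells grow exponentially at g_tumour and are killed by lesion
  CAR T-cells with phenotype-weighted rate sum_p kappa_p * pi_p(t).
* Blood CD19+ cells sit at the limit of quantitation and do not interact.

Units: counts are cells per 5.3 L blood (blood compartment) or cells per
lesion total (lesion compartment); rates are 1/day; killing constants are
1/(cell * day); lesion volume is cm^3 with v_cell cm^3 per tumour cell.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import response_criteria as rc

PHENOTYPES = ("naive", "cm", "em", "eff")

#: default simulation horizon, days post-infusion
HORIZON_DAYS = 30.0

#: solver tolerances (relative / absolute-scale factor)
RTOL = 1e-10
ATOL_SCALE = 1e-12

#: negative excursions within this many absolute tolerances of zero are
#: solver roundoff and clamped; anything larger raises
NEGATIVE_CLAMP_ATOLS = 100.0


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the offending parameters."""

    def __init__(self, message: str, params: "PatientParameters"):
        super().__init__(f"{message} (params={params.to_flat()})")
        self.params = params


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def _as_prop_vector(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (4,):
        raise ValueError(f"phenotype vector must have 4 entries, got shape {a.shape}")
    return a


@dataclass
class PatientParameters:
    """All per-patient rates, constants and initial conditions for models 1-5.

    Attributes
    ----------
    rho0 : float
        Initial antigen-independent proliferation rate, 1/day.
    gamma : float
        Exponential decay rate of the antigen-independent proliferation, 1/day.
    delta : float
        T-cell death rate shared by endogenous and CAR T-cells, 1/day.
    rho_a : float
        Maximal antigen-driven CAR proliferation rate, 1/day.
    K_half : float
        CD19+ cell count at half-maximal antigen stimulation, cells per lesion.
    g_tumour : float
        Lesion B-cell net growth rate, 1/day.
    kappa_p : ndarray (4,)
        Per-phenotype killing rate constants (naive, CM, EM, effector),
        1/(cell*day).
    phi : float
        Lesion:blood CAR T-cell partition ratio (C_l = phi * C_b).
    alpha_1, alpha_2, alpha_3 : float
        Differentiation rates naive->CM->EM->effector, 1/day.
    E0, C0 : float
        Initial blood endogenous / CAR T-cell counts, cells per 5.3 L.
    B0 : float
        Initial lesion CD19+ cell count, cells.
    pi_endo0, pi_car0 : ndarray (4,)
        Initial phenotype proportion vectors (sum to 1).
    B_blood_loq : float
        Constant blood CD19+ count at the limit of quantitation.
    v_cell : float
        Volume per tumour cell, cm^3.
    """

    rho0: float
    gamma: float
    delta: float
    rho_a: float
    K_half: float
    g_tumour: float
    kappa_p: np.ndarray
    phi: float
    alpha_1: float
    alpha_2: float
    alpha_3: float
    E0: float
    C0: float
    B0: float
    pi_endo0: np.ndarray
    pi_car0: np.ndarray
    B_blood_loq: float = 1e5
    v_cell: float = 1e-9

    def __post_init__(self):
        self.kappa_p = np.asarray(self.kappa_p, dtype=float)
        self.pi_endo0 = _as_prop_vector(self.pi_endo0)
        self.pi_car0 = _as_prop_vector(self.pi_car0)

    def validate(self) -> None:
        for name in ("rho0", "gamma", "delta", "rho_a", "g_tumour",
                     "alpha_1", "alpha_2", "alpha_3"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0, got {getattr(self, name)}")
        for name in ("E0", "C0", "B0", "B_blood_loq"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be >= 0, got {getattr(self, name)}")
        if np.any(self.kappa_p < 0):
            raise ValueError("killing rates kappa_p must be >= 0")
        for name in ("phi", "K_half", "v_cell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("pi_endo0", "pi_car0"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")

    # -- flat (scalar-per-key) representation, used by config files,
    #    population distributions, parameter alteration and sensitivity sweeps
    _VECTORS = {"kappa_p": "kappa", "pi_endo0": "pi_endo0", "pi_car0": "pi_car0"}

    def to_flat(self) -> dict:
        out = {}
        for name in ("rho0", "gamma", "delta", "rho_a", "K_half", "g_tumour",
                     "phi", "alpha_1", "alpha_2", "alpha_3", "E0", "C0", "B0",
                     "B_blood_loq", "v_cell"):
            out[name] = float(getattr(self, name))
        for i, p in enumerate(PHENOTYPES):
            out[f"kappa_{p}"] = float(self.kappa_p[i])
            out[f"pi_endo0_{p}"] = float(self.pi_endo0[i])
            out[f"pi_car0_{p}"] = float(self.pi_car0[i])
        return out

    @classmethod
    def from_flat(cls, d: dict, renormalize_props: bool = False) -> "PatientParameters":
        d = dict(d)
        kappa = np.array([d.pop(f"kappa_{p}") for p in PHENOTYPES])
        pe = np.array([d.pop(f"pi_endo0_{p}") for p in PHENOTYPES])
        pc = np.array([d.pop(f"pi_car0_{p}") for p in PHENOTYPES])
        if renormalize_props:
            pe = np.clip(pe, 0.0, 1.0)
            pc = np.clip(pc, 0.0, 1.0)
            pe = pe / pe.sum()
            pc = pc / pc.sum()
        return cls(kappa_p=kappa, pi_endo0=pe, pi_car0=pc, **d)

    def replace(self, **kw) -> "PatientParameters":
        return replace(self, **kw)


def endogenous_proliferation_rate(params: PatientParameters, t) -> np.ndarray | float:
    """Antigen-independent proliferation rate rho_e(t) = rho0 * exp(-gamma t).

    This rate applies to endogenous and CAR T-cells alike; its exponential
    decay encodes the waning of lymphodepletion-driven homeostatic expansion.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = params.rho0 * np.exp(-params.gamma * t)
    return float(out) if out.ndim == 0 else out


def model1_closed_form(params: PatientParameters, t) -> np.ndarray | float:
    """Analytic solution of model 1, dE/dt = (rho0 e^{-gamma t} - delta) E.

    E(t) = E0 * exp((rho0/gamma)(1 - e^{-gamma t}) - delta t); for gamma = 0
    the simple exponential E0 * exp((rho0 - delta) t) applies.
    """
    t = np.asarray(t, dtype=float)
    if params.gamma > 0:
        expo = (params.rho0 / params.gamma) * (1.0 - np.exp(-params.gamma * t)) \
            - params.delta * t
    else:
        expo = (params.rho0 - params.delta) * t
    out = params.E0 * np.exp(expo)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Dense simulated time courses for one patient and one model layer.

    Fields that a given layer does not define are ``None`` (e.g. model 1 has
    no CAR compartment). Lesion geometry assumes ``n_lesions`` equal spheres.
    """

    t: np.ndarray
    model_id: int
    params: PatientParameters
    n_lesions: int = 1
    E_b: Optional[np.ndarray] = None
    E_b_pheno: Optional[np.ndarray] = None      # (4, T) counts
    C_b: Optional[np.ndarray] = None
    C_l: Optional[np.ndarray] = None
    C_pheno_prop: Optional[np.ndarray] = None   # (4, T) proportions
    B_l: Optional[np.ndarray] = None
    lesion_volume: Optional[np.ndarray] = None  # cm^3
    lesion_diameter: Optional[np.ndarray] = None  # cm, per-lesion (equal)
    spd: Optional[np.ndarray] = None            # cm^2
    B_blood: Optional[np.ndarray] = None        # constant at LOQ

    _UNITS = {
        "E_b": "cells/5.3L", "C_b": "cells/5.3L", "C_l": "cells",
        "B_l": "cells", "B_blood": "cells/5.3L",
        "lesion_volume": "cm^3", "lesion_diameter": "cm", "spd": "cm^2",
    }

    def to_tidy(self) -> pd.DataFrame:
        """Export as tidy CSV-ready table (time_day, variable, value, unit, model_id)."""
        rows = []

        def emit(name, series, unit):
            for ti, v in zip(self.t, series):
                rows.append((ti, name, v, unit, self.model_id))

        for name, unit in self._UNITS.items():
            s = getattr(self, name)
            if s is not None:
                emit(name, s, unit)
        if self.E_b_pheno is not None:
            for i, p in enumerate(PHENOTYPES):
                emit(f"E_b_{p}", self.E_b_pheno[i], "cells/5.3L")
        if self.C_pheno_prop is not None:
            for i, p in enumerate(PHENOTYPES):
                emit(f"car_prop_{p}", self.C_pheno_prop[i], "1")
        return pd.DataFrame(rows, columns=["time_day", "variable", "value",
                                           "unit", "model_id"])

    def write_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_tidy(cls, df: pd.DataFrame,
                  params: Optional[PatientParameters] = None) -> "Trajectory":
        """Rebuild a trajectory from its tidy table (inverse of to_tidy)."""
        t = np.sort(df.time_day.unique().astype(float))
        model_id = int(df.model_id.iloc[0])
        traj = cls(t=t, model_id=model_id, params=params)

        def series(name):
            sub = df[df.variable == name].sort_values("time_day")
            return sub.value.to_numpy(dtype=float) if len(sub) else None

        for name in cls._UNITS:
            setattr(traj, name, series(name))
        eb = [series(f"E_b_{p}") for p in PHENOTYPES]
        if all(s is not None for s in eb):
            traj.E_b_pheno = np.vstack(eb)
        cp = [series(f"car_prop_{p}") for p in PHENOTYPES]
        if all(s is not None for s in cp):
            traj.C_pheno_prop = np.vstack(cp)
        return traj

    @classmethod
    def read_csv(cls, path,
                 params: Optional[PatientParameters] = None) -> "Trajectory":
        return cls.from_tidy(pd.read_csv(path, float_precision="round_trip"),
                             params=params)


def spd_from_cells(B_l, v_cell: float, n_lesions: int = 1):
    """Convert a lesion CD19+ cell count to (per-lesion diameter, SPD).

    Total volume V = B_l * v_cell is split evenly across ``n_lesions``
    spherical lesions; each has diameter d = (6 V / (n pi))^(1/3) and the sum
    of products of diameters is n * d^2 (equal-diameter lesions).
    """
    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    B_l = np.asarray(B_l, dtype=float)
    if np.any(B_l < 0):
        raise ValueError("cell count must be >= 0")
    V = B_l * v_cell
    d = np.cbrt(6.0 * V / (n_lesions * np.pi))
    spd = n_lesions * d ** 2
    if d.ndim == 0:
        return float(d), float(spd)
    return d, spd


def _chain_flux(x: np.ndarray, a1: float, a2: float, a3: float) -> np.ndarray:
    """Differentiation flux along the irreversible naive->CM->EM->EFF chain."""
    return np.array([
        -a1 * x[0],
        a1 * x[0] - a2 * x[1],
        a2 * x[1] - a3 * x[2],
        a3 * x[2],
    ])


def simulate(model_id: int, params: PatientParameters, t_grid: Sequence[float],
             n_lesions: int = 1, rtol: float = RTOL) -> Trajectory:
    """Integrate one of the five model layers over ``t_grid`` (days).

    The hierarchy is exact: models 2 and 4 reproduce model 1's endogenous
    total, and model 5's summed CAR phenotype counts reproduce model 3's CAR
    total, because proliferation and death are phenotype-uniform and model 3
    carries the phenotype-proportion chain internally to evaluate the
    effective killing rate sum_p kappa_p pi_p(t).
    """
    params.validate()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must be a 1-D array with >= 2 points")
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be sorted and start at 0")
    if model_id not in (1, 2, 3, 4, 5):
        raise ValueError(f"model_id must be in 1..5, got {model_id}")

    p = params
    fb = p.phi / (1.0 + p.phi)  # lesion fraction of total CAR cells

    def rho_e(t):
        return p.rho0 * np.exp(-p.gamma * t)

    def antigen(B):
        return p.rho_a * B / (B + p.K_half) if B > 0 else 0.0

    if model_id == 1:
        y0 = np.array([p.E0])

        def rhs(t, y):
            return [(rho_e(t) - p.delta) * y[0]]

    elif model_id == 2:
        y0 = np.array([p.E0, p.C0])

        def rhs(t, y):
            r = rho_e(t) - p.delta
            return [r * y[0], r * y[1]]

    elif model_id == 3:
        # states: E, C_T (total CAR), B, pi_car(4) auxiliary proportion chain
        y0 = np.concatenate([[p.E0, p.C0 * (1.0 + p.phi), p.B0], p.pi_car0])

        def rhs(t, y):
            E, CT, B = y[0], y[1], y[2]
            pi = y[3:7]
            r = rho_e(t) - p.delta
            kappa_eff = float(p.kappa_p @ pi)
            C_l = fb * CT
            return np.concatenate([[
                r * E,
                (r + antigen(B) * fb) * CT,
                p.g_tumour * B - kappa_eff * C_l * B,
            ], _chain_flux(pi, p.alpha_1, p.alpha_2, p.alpha_3)])

    elif model_id == 4:
        y0 = p.E0 * p.pi_endo0

        def rhs(t, y):
            r = rho_e(t) - p.delta
            return r * y + _chain_flux(y, p.alpha_1, p.alpha_2, p.alpha_3)

    else:  # model 5
        y0 = np.concatenate([
            p.E0 * p.pi_endo0,
            p.C0 * (1.0 + p.phi) * p.pi_car0,
            [p.B0],
        ])

        def rhs(t, y):
            Ep, Cp, B = y[0:4], y[4:8], y[8]
            r = rho_e(t) - p.delta
            CT = Cp.sum()
            pi = Cp / CT if CT > 0 else p.pi_car0
            kappa_eff = float(p.kappa_p @ pi)
            dEp = r * Ep + _chain_flux(Ep, p.alpha_1, p.alpha_2, p.alpha_3)
            dCp = (r + antigen(B) * fb) * Cp \
                + _chain_flux(Cp, p.alpha_1, p.alpha_2, p.alpha_3)
            dB = p.g_tumour * B - kappa_eff * fb * CT * B
            return np.concatenate([dEp, dCp, [dB]])

    atol = np.maximum(np.abs(y0), 1.0) * ATOL_SCALE
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, method="LSODA",
                    t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"ODE solver failed for model {model_id}: "
                              f"{sol.message}", params)

    y = sol.y
    if np.any(y < -NEGATIVE_CLAMP_ATOLS * atol[:, None]):
        raise SimulationError(
            f"negative state beyond clamp tolerance in model {model_id}", params)
    y = np.clip(y, 0.0, None)

    traj = Trajectory(t=t_grid, model_id=model_id, params=p, n_lesions=n_lesions)
    loq = np.full_like(t_grid, p.B_blood_loq)
    traj.B_blood = loq

    def set_lesion(B):
        traj.B_l = B
        traj.lesion_volume = B * p.v_cell
        d, spd = spd_from_cells(B, p.v_cell, n_lesions)
        traj.lesion_diameter = d
        traj.spd = spd

    if model_id == 1:
        traj.E_b = y[0]
    elif model_id == 2:
        traj.E_b, traj.C_b = y[0], y[1]
    elif model_id == 3:
        traj.E_b = y[0]
        CT = y[1]
        traj.C_b = CT / (1.0 + p.phi)
        traj.C_l = p.phi * traj.C_b
        set_lesion(y[2])
        pi = y[3:7]
        traj.C_pheno_prop = pi / pi.sum(axis=0, keepdims=True)
    elif model_id == 4:
        traj.E_b_pheno = y
        traj.E_b = y.sum(axis=0)
    else:
        traj.E_b_pheno = y[0:4]
        traj.E_b = y[0:4].sum(axis=0)
        Cp = y[4:8]
        CT = Cp.sum(axis=0)
        traj.C_b = CT / (1.0 + p.phi)
        traj.C_l = p.phi * traj.C_b
        with np.errstate(invalid="ignore", divide="ignore"):
            traj.C_pheno_prop = np.where(CT > 0, Cp / CT, p.pi_car0[:, None])
        set_lesion(y[8])
    return traj


# ---------------------------------------------------------------------------
# Derived outputs
# ---------------------------------------------------------------------------

@dataclass
class DerivedOutputs:
    """Scalar summaries of a trajectory used for response and sensitivity.

    cmax/tmax: peak blood CAR count and the earliest time it is attained;
    auc: trapezoid time-integral of the blood CAR count;
    prop_tumour_size_change: (V_end - V_start) / V_start;
    lugano_response: simplified Lugano class from the lesion history.
    """

    cmax: float
    tmax: float
    auc: float
    lugano_response: Optional[rc.ResponseClass] = None
    prop_tumour_size_change: Optional[float] = None

    def to_dict(self) -> dict:
        d = {"cmax": self.cmax, "tmax": self.tmax, "auc": self.auc}
        if self.prop_tumour_size_change is not None:
            d["propTmrSizeChange"] = self.prop_tumour_size_change
        if self.lugano_response is not None:
            d["luganoResponse"] = rc.ordinal(self.lugano_response)
        return d


def lesion_history_from_trajectory(traj: Trajectory) -> rc.LesionHistory:
    """Build the equal-lesion history (baseline/nadir/current) a classifier needs."""
    if traj.spd is None:
        raise ValueError(f"model {traj.model_id} trajectory has no lesion state")
    d = traj.lesion_diameter
    rec = rc.LesionRecord(baseline_d=float(d[0]), nadir_d=float(d.min()),
                          current_d=float(d[-1]))
    return rc.LesionHistory(
        baseline_spd=float(traj.spd[0]), current_spd=float(traj.spd[-1]),
        lesions=[rec] * traj.n_lesions, new_lesion=False)


def derived_outputs(traj: Trajectory) -> DerivedOutputs:
    """Compute peak/AUC/tumour-change/response summaries from a trajectory."""
    if traj.C_b is None:
        raise ValueError(f"model {traj.model_id} trajectory has no CAR compartment")
    C = traj.C_b
    i = int(np.argmax(C))  # earliest index attaining the max
    out = DerivedOutputs(
        cmax=float(C[i]),
        tmax=float(traj.t[i]) if C[i] > 0 else 0.0,
        auc=float(np.trapezoid(C, traj.t)),
    )
    if traj.lesion_volume is not None:
        V0, V1 = traj.lesion_volume[0], traj.lesion_volume[-1]
        out.prop_tumour_size_change = float((V1 - V0) / V0) if V0 > 0 else 0.0
        out.lugano_response = rc.classify(lesion_history_from_trajectory(traj))
    return out
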