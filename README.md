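# carpop

Population mechanistic modelling of month-one CAR T-cell dynamics in
lymphoma.

After infusion of an anti-CD19 CAR T-cell product, the first 30 days decide
much of the clinical outcome: the transferred cells expand, kill CD19⁺
tumour cells in the lesions, and decline. Two proliferation sources drive
this expansion — an antigen-*independent* component shared with the
patient's own (endogenous) T-cells, reflecting lymphodepletion-induced
homeostatic signalling, and an antigen-*dependent* component from CD19
stimulation inside lesions. `carpop` provides the modelling machinery to
quantify both from trial-style longitudinal data, and to ask what product or
patient changes would do to the response. It is written for quantitative
systems pharmacology and mathematical-immunology work where the clinical
tables themselves are typically proprietary: a bundled synthetic-cohort
generator with known ground truth makes every stage of the pipeline testable.

## The models

Five nested ODE layers ("Russian doll" construction — each layer extends the
previous ones without changing them):

1. endogenous T-cells in blood,
2. endogenous + CAR T-cells in blood,
3. endogenous + CAR T-cells in blood and lesion, with CD19⁺ target cells,
4. endogenous T-cells and their phenotypes in blood,
5. the full system: both cell types, four phenotypes, blood and lesion.

The core rates, per patient:

- antigen-independent proliferation decays exponentially after
  lymphodepletion, ρ_e(t) = ρ₀·e^(−γt), and acts on endogenous and CAR
  T-cells alike;
- both cell types die at a shared rate δ;
- lesion CAR T-cells receive extra antigen-driven proliferation
  ρ_a·B/(B + K) with saturating dependence on the CD19⁺ count B;
- CAR T-cells partition between blood and lesion at a constant ratio
  C_l = φ·C_b (extravasation fast relative to proliferation and death);
- lesion CD19⁺ cells grow at g and are killed at rate Σ_p κ_p π_p(t)·C_l,
  weighted by the CAR phenotype composition π(t);
- phenotypes (naïve → central memory → effector memory → terminal effector)
  differentiate irreversibly at rates α₁..α₃ with phenotype-uniform
  proliferation, so totals are independent of composition.

Counts are per 5.3 L blood (blood) or per lesion (lesion); lesion geometry
converts cell counts to diameters and the radiological sum of product of
diameters (SPD). A simplified 2014 Lugano classifier turns lesion histories
into CR/PR/SD/PD calls.

On top of the models: sequential individual fitting with parameter freezing,
two-stage population-distribution estimation, virtual-patient cohorts with
parameter-alteration experiments, a five-technique sensitivity suite (eFAST,
random-forest importances, Spearman correlations, local 1% perturbation —
each with a dummy-parameter noise floor), proliferation-source
decomposition, tiered responder ranking, cytokine-covariate correlation and
LDH-based tumour-burden interpolation.

## Worked example

```python
import numpy as np
from carpop import (simulate, derived_outputs, default_patient,
                    decompose_proliferation)

p = default_patient()                      # typical post-lymphodepletion patient
t = np.linspace(0, 30, 31)
traj = simulate(5, p, t)                   # full model, daily grid
out = derived_outputs(traj)
print(f"Cmax  = {out.cmax:.3g} CAR T-cells per 5.3 L blood")
print(f"tmax  = {out.tmax:.0f} days")
print(f"AUC   = {out.auc:.3g} cell-days")
print(f"tumour change = {out.prop_tumour_size_change:+.1%}")
print(f"response = {out.lugano_response.value}")
dec = decompose_proliferation(p, traj)
print(f"day-0 proliferation: endogenous {dec.endogenous[0]:.2f}/day, "
      f"antigen-driven {dec.antigen[0]:.2f}/day")
```

prints

```
Cmax  = 1.6e+08 CAR T-cells per 5.3 L blood
tmax  = 15 days
AUC   = 2.53e+09 cell-days
tumour change = -99.0%
response = CR
day-0 proliferation: endogenous 0.90/day, antigen-driven 0.42/day
```

i.e. this patient's CAR T-cells expand ~80-fold to a peak on day 15, the
lesion shrinks by 99% (a complete response), and at infusion the
lymphodepletion-driven proliferation (0.90/day) is roughly twice the
antigen-driven rate (0.42/day) — the two sources are comparable, with the
endogenous one ahead.

The same flow runs from the shell:

```bash
carpop pipeline --seed 1 --out runs/demo        # generate → fit → vpop → classify
carpop classify --in lesions.csv --out responses.csv
```

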