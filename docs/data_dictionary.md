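# Synthetic cohort data dictionary

A generated cohort directory contains five CSV tables. All values are plain
decimal; write/read round-trips are lossless to full float precision.

## observations.csv

One row per measurement.

| column     | type  | description |
|------------|-------|-------------|
| patient_id | str   | `P000`, `P001`, ... |
| time_day   | float | days post-infusion, 0–30 |
| observable | str   | see below |
| value      | float | measurement in `unit` |
| unit       | str   | `cells/5.3L`, `cm^2`, or `1` (dimensionless) |

Observables: `E_blood` (blood endogenous T-cell count), `C_blood` (blood
CAR⁺ T-cell count), `cd19_blood` (blood CD19⁺ count, constant at the limit
of quantitation), `spd` (sum of product of lesion diameters, cm²; first and
last imaging visit only), `endo_prop_{naive,cm,em,eff}` and
`car_prop_{naive,cm,em,eff}` (flow-style phenotype proportions, each visit's
four values sum to 1).

## lesions.csv

| column     | type  | description |
|------------|-------|-------------|
| patient_id | str   | |
| lesion_id  | int   | 0-based |
| baseline_d | float | longest diameter at day 0, cm |
| final_d    | float | longest diameter at the final visit, cm |

## covariates.csv

| column     | type  | description |
|------------|-------|-------------|
| patient_id | str   | |
| time_day   | float | |
| covariate  | str   | `LDH` (arbitrary units), `IL7`, `IL15` (normalized) |
| value      | float | |

## truth.csv

Generating ground truth, one row per (patient, parameter) with flat
parameter names (`rho0`, `gamma`, `delta`, `rho_a`, `K_half`, `g_tumour`,
`kappa_{naive,cm,em,eff}`, `phi`, `alpha_1..3`, `E0`, `C0`, `B0`,
`pi_endo0_*`, `pi_car0_*`, `B_blood_loq`, `v_cell`). Units as in the
`PatientParameters` docstring.

## population.csv

The truth population model: `parameter`, `family`
(`normal`/`lognormal`/`logitnormal`), `location`, `scale` — location and
scale on the family's latent Gaussian scale.
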