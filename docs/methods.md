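# Methods

This note documents the model equations, the statistical machinery, the
synthetic-data generator, and the numerical and design choices behind
`carpop`, in the spirit of the methods documentation that simulation
packages ship alongside their APIs.

## Model equations

All five layers share the antigen-independent ("endogenous-driven")
proliferation rate

    rho_e(t) = rho0 * exp(-gamma * t)        [1/day]

which captures the surge and decay of homeostatic proliferation after
lymphodepleting chemotherapy, and a common death rate delta. Time t = 0 is
the infusion day; the default horizon is 30 days, the early expansion and
first decline phase. The model deliberately has no homeostatic floor: at
late times endogenous counts decay toward zero, which is a known
mis-specification beyond the first month and the reason the horizon is
capped.

Layer 1 (endogenous blood count E):

    dE/dt = (rho_e(t) - delta) * E

Layer 2 adds the blood CAR count with the same net rate (no lesion, hence no
antigen stimulation).

Layer 3 adds the lesion. The total CAR count C_T distributes between blood
and lesion at a fixed ratio, C_l = phi * C_b with C_T = C_b + C_l,
a quasi-equilibrium justified when extravasation is fast compared with
proliferation, killing and death. Antigen stimulation acts on the lesion
fraction only:

    dC_T/dt = [rho_e(t) - delta + rho_a * B/(B + K_half) * phi/(1+phi)] * C_T
    dB/dt   = g_tumour * B - (sum_p kappa_p * pi_p(t)) * C_l * B

where B is the lesion CD19+ count and pi(t) the CAR phenotype proportions.
The Michaelis form B/(B + K_half) is the simplest one-constant saturation
for antigen-limited stimulation. Blood CD19+ cells sit pinned at the limit
of quantitation and do not interact with CAR T-cells; all CAR-target
interaction happens in the lesion.

Layers 4 and 5 add the phenotype chain naive -> CM -> EM -> effector with
differentiation rates alpha_1..3. Proliferation and death are
phenotype-uniform, so the chain moves cells between compartments without
changing totals: layer 4's summed phenotypes reproduce layer 1 exactly, and
layer 5's summed CAR phenotypes reproduce layer 3. Because killing is
phenotype-weighted (by default kappa_naive = kappa_cm = 0 and
kappa_em = kappa_eff free — effector-weighted killing is the only
phenotype-dependent channel), layer 3 integrates the phenotype-proportion
chain as auxiliary states to evaluate the same effective killing rate;
without this the two layers would disagree about the tumour whenever the
proportions drift. The proportion chain is autonomous (independent of
counts), which is what makes this consistent.

Lesion geometry: tumour cells have identical volume v_cell, lesions are
spheres of equal diameter, and elimination is even across lesions, so
V = B * v_cell, d = (6V/(n*pi))^(1/3), and SPD = n * d^2. T-cells do not
contribute to lesion volume.

### Numerical integration

LSODA (stiff-capable) with rtol 1e-10 and per-state atol of 1e-12 times the
initial-state scale. The tight tolerances are cheap at this dimension
(<= 9 states) and make the hierarchy identities hold to ~1e-10 relative,
comfortably inside the 1e-6 documented contract. When the tumour collapses
over many decades the solver can overshoot zero by an amount on the order of
the absolute tolerance; negative excursions within 100 atol are clamped to
zero, anything larger is treated as a solver failure and raised with the
offending parameters attached.

## Response classification

The simplified 2014 Lugano rules operate on lesion diameter histories:
CR needs an SPD reduction of at least 50% (inclusive) and every lesion
strictly under 1.5 cm; PR needs the 50% reduction alone; PD needs an SPD
increase of at least 50%, a diameter strictly above 1.5 cm and growth from
nadir of at least 0.5 cm (diameter < 2 cm) or 1.0 cm (otherwise), or a new
lesion; SD is the residual class. The rules as written overlap, and no
precedence is stated; we evaluate PD first (it references the nadir and must
dominate), then CR, then PR, with SD residual. The < 2 cm branch of the
nadir rule is chosen by the *current* diameter, the literal reading. The
PET five-point scale, bone-marrow and spleen criteria of the full 2014
Lugano system are out of scope.

## Fitting

Individual fits minimize a weighted least-squares objective equivalent to a
Gaussian log-likelihood with a proportional error model on counts and SPD
(residuals on the log scale, sigma 0.25) and an additive logit-scale model
on proportions (sigma 0.2). Optimization is bounded local search
(`scipy.optimize.least_squares`, trust-region reflective) on transformed
coordinates — log for positive parameters, additive-log-ratio for simplex
proportions — from configuration-supplied initial values with seeded,
jittered restarts. A +/-10 box (in log units) around the start prevents
runaway along structurally flat directions such as a saturated Michaelis
constant. Transformed coordinates are all O(1), so unit x-scaling is used.

Layers are fit sequentially, 1 through 5, each freezing the parameters
finalized by its predecessors: layer 1 owns (E0, rho0, gamma, delta) from
blood endogenous counts; layer 2 initialises C0 from blood CAR counts;
layer 3 owns (C0, rho_a, K_half, g_tumour, kappa, B0) from blood CAR counts
plus SPD; layer 4 owns (alpha_1..3, pi_endo0) from endogenous phenotype
proportions; layer 5 owns pi_car0 from CAR phenotype proportions. Two
choices deserve comment:

- C0 is owned by layer 3, not layer 2. In the lesion-free layer 2 the CAR
  equation has no antigen stimulation, so fitting C0 there against data that
  do contain antigen-driven expansion folds the whole expansion into the
  initial count. Layer 2 provides the starting value; layer 3, where the
  confounding is resolved, finalizes it.
- After the phenotype layers, layer 3's own parameters are re-fit once with
  the final phenotype estimates. The effective killing rate depends on the
  CAR phenotype composition, which is only known after layer 5; the single
  refinement pass removes the small bias from fitting the tumour layer at
  provisional phenotype values. The freezing contract is kept throughout:
  no layer ever moves a parameter owned by another layer.

phi, the lesion:blood partition ratio, is structurally non-identifiable from
blood counts and SPD alone (it enters only through products with rho_a and
kappa) and stays frozen at its configured value; correspondingly the default
synthetic truth population gives it zero spread.

Population estimation is two-stage: individual optima first, then Gaussian
maximum-likelihood moments of each parameter's optima on its family's latent
scale (identity for normal, log for lognormal, logit for logit-normal
parameters; proportions are always logit-normal). Latent-scale Pearson
correlations are estimated on request, and observation-error magnitudes come
from pooled residuals. This deliberately replaces population-likelihood
(SAEM-style) estimation from NLME software — the single largest
methodological substitution in the package. Two-stage estimates are known to
inflate the population spread when individual data are weak (shrinkage is
absent); the acceptance experiments use location recovery within standard
errors, which is robust to this.

Downstream analyses: the proliferation decomposition reports
rho_e(t) against rho_a*B(t)/(B(t)+K_half) per compartment (zero antigen
drive in blood); responder ranking is a stable lexicographic sort on ordinal
(month 1, month 3, month 6) grades (CR=0 < PR=1 < SD=2 < PD=3), split into
equal good/poor halves; covariate correlation is per-patient Spearman with
the covariate interpolated onto the rate grid; LDH interpolation maps the
LDH series affinely onto the (start, end) SPD pair, falling back to
linear-in-time when LDH is flat.

## Sensitivity suite

Five techniques, from global to local, all applied to the same outputs:
Cmax, tmax, AUC of the blood CAR count, the ordinal-coded Lugano class, and
the proportional tumour-size change. AUC is retained even though it tracks
Cmax closely.

- eFAST is implemented in-package (first-order SI and total TSI). Search
  curves place the driver parameter at omega_max = (N-1)/(2M) and the
  complement at interference-separated low frequencies, with a random phase
  per resampling curve; the interference factor M is 4. N samples per
  parameter, D parameters (plus dummy), and M_r resampling curves give
  N*D*M_r model runs — 188,000 at the full-scale setting of N=1000, D=47,
  M_r=4. Designs too small for distinct complementary frequencies are
  rejected with the minimal valid N. On the additive two-parameter test
  function the implementation reproduces the analytic 0.5/0.5 variance
  shares within 0.01, and on the product (interaction-only) function SI ~ 0,
  TSI ~ 1.
- Random-forest importances (100 trees, scikit-learn defaults) trained on
  all rows — the forest is never used for prediction, so no held-out split.
  Three data sources are supported: the global eFAST sample, virtual-patient
  draws, and per-patient optima.
- Spearman rank correlation on the same virtual patients or optima.
- Local: each optimum parameter perturbed +/-1%; the score is the mean
  absolute relative output change over patients and both directions.

Global bounds are the population location +/-3 scales on each parameter's
latent scale, transformed to natural units and truncated to (eps, 1-eps) for
proportions; zero-spread parameters are excluded. A dummy parameter on
[0, 1] rides along in the stochastic methods; heatmap normalization
subtracts the dummy's apparent index per row where applicable, floors at
zero, and scales each row to unit maximum (magnitudes are used for signed
Spearman entries). Failed model runs inside global sweeps are NaN, imputed
by the output median when under the 1% (index estimation) / 5% (sweep)
caps, otherwise the run aborts.

## Synthetic cohorts

The generator emulates the data streams of an early-phase CAR T-cell trial,
with known ground truth: per-patient parameters drawn from a truth
population, the full model simulated, and observations sampled on a
trial-like schedule (blood days 0/1/3/5/7/10/14/21/28, weekly phenotyping,
imaging at days 0 and 28 only, twice-weekly LDH; all configurable). The
default cohort size is 64 patients.

Default truth population (chosen once, as a realistic post-lymphodepletion
large-B-cell-lymphoma cohort): rho0 lognormal around 0.9/day and gamma
around 0.12/day (strong homeostatic proliferation decaying on a ~8-day
timescale, yielding ~50-100x CAR expansion peaking around day 15); delta
Gaussian 0.20 +/- 0.02/day; rho_a lognormal around 0.5/day (antigen-driven
proliferation roughly half the initial endogenous-driven rate, so the two
sources are comparable with the endogenous one ahead); K_half ~ 2e9 cells;
B0 ~ 1e10 cells (a ~10 cm^3, ~2.7 cm lesion at v_cell = 1e-9 cm^3);
g_tumour ~ 0.02/day; kappa_em = kappa_eff ~ 1e-8 /(cell*day) (tied, matching
the effector-weighted killing design); C0 ~ 2e6 cells per 5.3 L; E0 ~ 1e8
(lymphodepleted); differentiation rates ~0.05-0.08/day; initial phenotype
splits logit-normal around CM/EM-dominated products. Lognormal spreads of
0.15-0.5 give the order-of-magnitude inter-patient variability typical of
CAR expansion data.

Deliberate artefacts of real trial tables are reproduced: SPD only at the
first and last imaging visit; blood CD19+ pinned constant at the limit of
quantitation; LDH generated as 200 + 10*V(t) arbitrary units plus additive
noise (a tumour-burden surrogate by construction); IL-7/IL-15 as
a*exp(-gamma_i*t) + b plus noise using the patient's own decay rate, so the
correlation between cytokines and the endogenous proliferation rate exists
by construction (the generator encodes the hypothesis; recovering the
correlation tests the analysis machinery, not the biology). Uniform
missingness can be layered on, never dropping the baseline visit.

What passing tests on these cohorts do *not* show: that the model family is
correctly specified for real patients; that phi is constant in vivo; that
LDH is a faithful burden surrogate; or that the cytokine correlation is
causal. The generator draws from the same model family that is fit, so
recovery tests validate the inference machinery under correct
specification — the strongest claim synthetic data can support.

## Pipeline and reproducibility

A single master seed fans out to per-stage seeds via
`numpy.random.SeedSequence` spawning (stage index into a fixed stage list),
so stages are individually reproducible and cannot collide. Identical seeds
give bitwise-identical parameter draws and datasets. Every pipeline run
writes a provenance record (config hash, master seed, package version) and a
file manifest; configs are YAML with unknown keys rejected by key path.

Problem sizes in the shipped tests and acceptance experiments: single-patient
recovery uses daily noise-free sampling of every stream (the fitting
machinery's correctness check, independent of the sparse default schedule);
population recovery uses 20 noisy patients on the default schedule;
hierarchy conservation uses 100 random draws; alteration experiments use 200
virtual patients; eFAST oracles run at N=1000 on analytic test functions.
These sizes were chosen to exercise each claim at desk scale.

## Known limitations

- No second, slower decline phase: beyond ~30 days the model predicts
  indefinite decline of both cell populations.
- No endogenous anti-tumour response, no exhaustion state, no cytokine
  state variables (cytokines enter only as generated covariates), no tumour
  microenvironment, no toxicity (CRS/neurotoxicity) modelling.
- Killing feedback on CAR proliferation operates only through B-cell
  depletion.
- Two-stage population estimation inflates spread estimates relative to
  joint NLME fits when individual data are sparse or noisy.
- The proportion renormalization applied after parameter alteration
  (cap at 1, then renormalize the simplex) is one of several defensible
  conventions; it honours the multiplicative intent for small baseline
  proportions while keeping the vector valid.
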