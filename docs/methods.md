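# Methods

## Structural model

SPIR and CAN kinetics are described by a linear five-state compartmental
system: oral depot, SPIR central/peripheral, CAN central/peripheral. The
depot empties with first-order rate `ka` after an absorption lag `ALAG1`,
implemented as an exact time shift of each dose's input (NONMEM ALAG
semantics), not as a transit-compartment approximation. SPIR leaves its
central compartment with total clearance

    CL_tot = CL·(1 − Fm) + CLM1·Fm,

of which the fraction-metabolized share `Fm·CLM1` forms CAN; CAN is cleared
by `CLM`. Two readings of `Fm` are possible in a parent–metabolite model; we
adopt the one in which SPIR central elimination is `CL_tot/V2` and the CAN
formation rate constant is `Fm·CLM1/V2`, because it is the only reading
under which the total-clearance identity above holds and the metabolite
mass balance `AUC_CAN = Dose·Fm·CLM1/(CL_tot·CLM)` follows. All clearances
and volumes are apparent (conditioned on the unidentified oral
bioavailability F). Internal units are mg, L, h; concentrations are mg/L
with a ×1000 display conversion to ng/mL at the I/O layer only.

Adult typical values (`ADULT_TYPICAL`): CL 629, CLM1 217, Q 89.9, CLM 17,
Q1 60 L/h; V2 517, V3 777, V4 189, V5 448 L; ka 5.22 1/h; ALAG1 0.156 h;
Fm 0.7 (fixed).

### Solver

Because the system is linear and time-invariant and doses are depot boluses,
the profile is the superposition of impulse responses. We eigendecompose the
5×5 rate matrix once per parameter set and evaluate
`V exp(Λ(t−t_dose−lag)) V⁻¹ e_depot` vectorized over the grid; a segment-wise
`scipy.linalg.expm` propagation is the fallback when the eigenbasis is
ill-conditioned (near-defective matrices, e.g. `ka` colliding with a
disposition eigenvalue). A stiff LSODA integration path
(`solve_profile_ode`) exists purely as a cross-check; the two agree to 1e−8
relative in the test suite. The exact solver makes a single profile ~0.2 ms,
which is what keeps the Monte Carlo layers cheap.

### Terminal slopes

`terminal_slope` returns the smallest non-zero rate among the exponentials
feeding an analyte: the parent disposition eigenvalues (2×2 closed form),
plus the CAN disposition eigenvalues for the metabolite, plus `ka` unless
excluded. When absorption is slower than disposition (fed state,
ka = 0.339 1/h) the reported slope is `ka` — flip-flop kinetics fall out of
the rate comparison with no special casing.

## Between-subject variability and residual error

Individual parameters follow `P_i = P_typ·exp(η_i)` with variances (ω²):
ka 0.9, CL 0.166, V2 0.118, Q 0.08, CLM1 0.18, CLM 0.08, V4 0.03, Q1 0.07,
V5 0.09, and covariance 0.112 between the CL and V2 effects (drawn through
the Cholesky factor of the 2×2 block; an exactly singular block gets a
1e−12 jitter and a warning). ALAG1, Fm and V3 carry no variability.
Residual error is proportional per analyte, `obs = pred·(1 + ε)`, with
variances (NONMEM SIGMA convention) 0.08 for SPIR and 0.017 for CAN.
Negative observations after noise are floored at zero and counted in the
log rather than redrawn; η are not truncated. Adult variability is carried
unchanged to all pediatric simulation.

## Allometric bridging

Pediatric typical values are `P_adult·(WT/70)^b`, b = 0.75 for all
clearances (CL, CLM1, CLM, Q, Q1), b = 1 for all volumes, b = 0 for ka,
ALAG1 and Fm. The eight default median weights (2, 6, 12, 17 years × sex)
are recovered by inverting the exponent-1 volume rule from the published
pediatric central volumes (weight = 70·V2_ped/517), so the grid is
self-reproducing without an external growth-chart download; a user CSV can
replace them for other ages. Two quirks of the published grid are preserved
deliberately: the pediatric lag prints as 0.160 h but is treated as a
rounding of the unscaled adult 0.156 h, and the 17-year female implied
weight (64.19 kg) exceeds the male one (54.71 kg) — reproduced as printed,
not "corrected". The half-open age bracket (2 to <17, plus 17 itself as the
oldest reference age) is enforced at cohort construction, not inside the
scaling arithmetic.

## Scenarios

Cirrhosis multiplies CL by 0.1556, CLM1 by 0.6224 and CLM by 0.2845; the
fed state multiplies ka by 0.065, Fm by 0.40 and the dose-scale
(bioavailability) by 2. The fed bioavailability doubling rides on
`dose_scale` because every parameter is F-conditioned — doubling the
effective dose is algebraically identical. The two flag sets touch disjoint
parameters and compose multiplicatively; applying a scenario to a set that
already carries one raises instead of silently compounding. Note that the
fed Fm reduction raises CL_tot (CL·0.72 + CLM1·0.28 = 513.6 L/h), so the
fed/fasted SPIR AUC ratio is 2·340.6/513.6 ≈ 1.33 rather than the naive 2.
An optional strict flip-flop mode additionally rescales the parent
clearances so the central elimination rate constant equals the reduced ka;
it exists for sensitivity comparison only, since the ka reduction alone
already produces absorption-limited kinetics.

## Exposure metrics and dose selection

NCA uses the linear-up/log-down trapezoid for AUC to the last observation;
λz comes from a log-linear fit over the suffix window (≥3 points strictly
after Cmax, positive concentrations) maximizing adjusted R², and
AUC_inf = AUC_last + C_last/λz, reported as missing when no acceptable
terminal fit exists. AUC_inf is the headline exposure metric.

Dose selection simulates, per dose and reference age, 100 virtual subjects
per sex under the chosen scenario, computes each subject's noise-free
AUC_inf (the exposure spread reflects between-subject variability, not assay
error), and compares the cohort mean against an adult reference cohort of
200 subjects at 70 kg given the fixed mapped dose (0.25 and 0.5 mg/kg vs
25 mg; 1, 1.5 and 2 mg/kg vs 100 mg) under the same scenario. The adequacy
rule is the pediatric mean falling inside the adult 5th–95th percentile
band (the mean±SD band is also flagged); no numeric equivalence bound is
defined. Simulation grid: 0–336 h, dense (0.05 h) through absorption.

## Sparse sampling design

Three age groups (12–<17, 6–<12, 2–<6 years), six subjects each by default,
randomized 1:1 into two interleaved day-1 window sets that pool to cover
0.08–8 h; every subject adds one sample in each of the 46–50 h and
166–170 h windows (6 samples per subject in group 1, 5 in groups 2–3). One
time is drawn uniformly per window; both analytes are assayed at every draw
(one blood draw measures both). Doses are 0.5 mg/kg at full precision (no
syringe-graduation rounding). Datasets use the NONMEM event/observation
dialect (ID, TIME, AMT, DV, CMT, EVID, MDV + WT/AGE/SEX; CMT 1 = depot,
2 = SPIR, 4 = CAN; "." for missing) and round-trip losslessly through the
CSV reader/writer.

For design evaluation the three groups are represented by the reference
ages 12, 6 and 2 years (the youngest age of each group bracket for the two
upper groups is deliberately conservative for the smallest weights), with
sexes alternating for the weight lookup.

## Design evaluation

Two routes quantify expected estimation precision, sharing the estimated
set (CL, CLM1, V2, CLM, V4, ka — the six exposure-relevant fixed effects;
the rest are fixed, since 18 subjects × ≤6 samples cannot inform twelve
fixed effects plus ten variance components; the set is configurable).

**Fisher information (FO).** The mixed-effects model is linearized at
η = 0. Per subject, with `f` the typical prediction vector, `J = ∂f/∂θ`
(central differences on log θ, step 1e−4) and `G = ∂f/∂η`, the observation
covariance is `V = G Ω G′ + diag(σ² f²)`. Rows are whitened by `1/(σ·f)` so
`V_w = G_w Ω G_w′ + I` stays well conditioned across the profile's dynamic
range (avoiding an absolute ridge that would otherwise swallow the
information in near-zero late concentrations). Observations at which the
typical prediction is exactly zero (pre-lag window draws) are dropped as
information-free. `FIM = Σ_i J_w′ V_w⁻¹ J_w`; %RSE = 100·√diag(FIM⁻¹)/θ,
i.e. relative to the typical value (NONMEM convention). A singular FIM
raises an error naming the dominant non-identifiable direction.

**Pooled estimator (simulation/re-estimation).** Each replicate simulates a
fresh sparse study (BSV + residual error) and re-estimates the
adult-referenced θ by generalized least squares on log-concentrations: all
subjects are tied to one θ through the fixed-exponent allometric rule;
optimization is Levenberg–Marquardt in log-parameter space with up to three
perturbed restarts (CV 20%). BSV enters through moment-matching: the
marginal mean `E[log f(θ e^η)]` and within-subject covariance
`Cov[log f] + σ² I` are computed by antithetic Monte Carlo over η (256
draws, fixed internal seed so fits are deterministic), and each subject's
residual vector is centred and whitened accordingly. The full covariance —
not just a variance inflation — matters: shared η correlate a subject's
observations, and ignoring that correlation left the typical ka and V2
essentially unidentified in sparse data (multi-fold empirical variance and
double-digit bias in development experiments; simpler diagonal and
second-order-Taylor variants were rejected on the same grounds). Moments
are evaluated at the initial (reference) values — the natural linearization
point in design evaluation, where the simulation truth plays that role —
with `n_outer` available to re-evaluate at the running estimate. Asymptotic
%RSE comes from `s²(J′J)⁻¹` at the optimum (log-space, hence directly
relative); empirical %RSE across replicates is `100·sd(θ̂)/θ_true`.
Observations with zero DV (floored noise) or before the lag are excluded;
the exclusion set is fixed because the lag is not estimated. For the rich
adult synthetic study the allometric tie is disabled (`allometric=False`),
matching the generator, which carries no weight effect. This pooled GLS is
a first-order population estimator, not a full nonlinear mixed-effects
(Laplace/FOCEI) implementation — that remains out of scope.

Under the default design the FIM route gives a maximum %RSE of ≈30% (ka;
all others ≈10–13%), and 100 simulation/re-estimation replicates agree with
the FIM prediction within a factor of ~1.3 per parameter with 100%
convergence.

## Synthetic adult data

The adult stand-in emulates the pooled phase-I studies: 14 subjects at
25 mg and 78 at 100 mg (92 total), single dose, fasted, with the full BSV
and residual model; weights are drawn N(64.1, 6.4²) kg truncated below
40 kg for covariate realism although the adult model ignores weight. The
rich grid (0.25–120 h, 16 samples) is a declared assumption — the actual
phase-I schedules are not public — chosen to span absorption through the
CAN terminal phase (t½ ≈ 30 h). A 23-subject fed/fasted crossover generator
reuses each subject's η across periods with a 336 h washout offset. The
excluded protocol-deviation subject of the real pilot study is represented
only by the 92-subject count. `generate_truth_bundle` returns the dataset
together with the generating parameters and per-subject η for recovery
tests.

What the generator does not emulate: assay quantification limits (no LLOQ
censoring), demographic covariate effects, inter-occasion variability, and
multiple-dose accumulation. Passing recovery tests therefore demonstrate
estimator correctness under the assumed statistical model, not robustness
to real-data pathologies.

## Numerical choices and problem sizes

- Eigen-solver fallback threshold: basis condition number 1e10.
- Mass-balance and AUC identities verified on dense grids to 2000 h (0.5%
  tolerance, trapezoid discretization dominating).
- Terminal regression requires ≥3 points after Cmax; ties broken by
  adjusted R².
- Dose-selection runs use N = 200 per age (100 per sex) and N = 200 adult
  reference subjects; design evaluation uses 18 subjects and 100
  replicates. These match the stated study dimensions and complete in
  seconds to ~2 minutes.
- All randomness flows through `numpy.random.Generator` seeded explicitly;
  identical seeds give bitwise-identical cohorts, datasets and CSVs.

## Known limitations

- Linear kinetics only: no saturable metabolism, no IV route, no TMS or
  other metabolites, no protein-binding model.
- The pooled GLS estimator is a stand-in for a full NLME fit; its %RSE
  under-reports nothing observed in testing, but variance components are
  not re-estimated (Ω and σ² are taken as known when whitening).
- Extrapolation below 2 years is out of scope (no maturation functions).
- Cirrhosis modifiers keep adult variability unchanged; severity grades are
  not modelled.
- The exposure comparison is a band-inclusion rule, not a bioequivalence
  test with confidence intervals.
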