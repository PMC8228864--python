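# spirped — pediatric trial simulation for a spironolactone oral suspension

Spironolactone (SPIR) has been given to children off-label for decades, but
no liquid formulation carries a pediatric label and no pediatric dosing is
established. `spirped` implements the model-informed workflow used to design
a first pediatric pharmacokinetic trial of a SPIR oral suspension in patients
aged 2 to <17 years with edema: it simulates the joint kinetics of SPIR and
its active metabolite canrenone (CAN), bridges adult population estimates to
children, selects weight-based doses by Monte Carlo comparison against adult
reference exposures, and evaluates a blood-sparing windowed sampling design.
It is written for pharmacometricians and trial statisticians.

## The model

SPIR and CAN each follow a two-compartment disposition model, linked by
first-order absorption from an oral depot with lag `ALAG1`:

    depot --ka--> SPIR central (V2) <--Q--> SPIR peripheral (V3)
                      |
                      |  total clearance  CL_tot = CL·(1−Fm) + CLM1·Fm
                      |  formation flux   Fm·CLM1·C_SPIR
                      v
                  CAN central (V4) <--Q1--> CAN peripheral (V5) --CLM-->

All clearances and volumes are apparent (F-conditioned); a `dose_scale`
multiplier carries bioavailability changes such as the fed-state doubling.
The linear system is solved exactly by eigendecomposition of the five-state
rate matrix (a stiff ODE path is kept for cross-checks).

Around this core the package provides:

* **Population variability** — log-normal between-subject variability on nine
  parameters with a (CL, V2) covariance, proportional residual error per
  analyte (`population.py`).
* **Allometry** — fixed-exponent scaling `P_ped = P_adult (WT/70)^b` with
  b = 0.75 for clearances, 1 for volumes (`allometry.py`).
* **Scenarios** — cirrhosis (CL −84.44%, CLM1 −37.76%, CLM −71.55%) and
  high-fat-meal (ka −93.5%, bioavailability ×2, Fm −60%) modifiers
  (`scenarios.py`).
* **Exposure metrics** — noncompartmental AUC/Cmax/λz and Monte Carlo dose
  sweeps against adult 25/100 mg reference bands (`exposure.py`).
* **Trial design** — the windowed sparse sampling schemes (6 samples per
  subject at 12–<17 y, 5 below) and NONMEM-style dataset simulation
  (`design.py`).
* **Design evaluation** — expected %RSE by first-order population Fisher
  information and empirical simulation/re-estimation with a moment-matched
  pooled estimator (`evaluation.py`).
* **Synthetic data** — rich-sampled 92-subject adult study stand-ins with
  known ground truth for recovery experiments (`synthetic.py`).

## Worked example

```python
import spirped as sp

# 1. bridge the adult estimates to the pediatric reference ages
table = sp.rebuild_pediatric_table()
print(table[["age", "sex", "weight_kg", "cl", "v2", "clm1", "clm"]].head(4))

# 2. does 0.5 mg/kg reproduce the adult 25 mg exposure?
sweep = sp.dose_sweep(doses=(0.5,), ages=(2, 17), n_per_sex=100, rng=7)
print(sweep[["age", "analyte", "ped_mean", "ref_p5", "ref_p95", "inside_pi"]])

# 3. how precisely can the sparse design estimate the parameters?
fim = sp.expected_rse_fim(sp.reference_sparse_design(rng=1))
print(fim.rse)
```

which prints

```
  age sex  weight_kg     cl     v2   clm1   clm
adult   -      70.00 629.00 517.00 217.00 17.00
    2   F      12.63 174.13  93.28  60.07  4.71
    2   M      11.78 165.26  87.00  57.01  4.47
    6   F      21.59 260.33 159.46  89.81  7.04

 age analyte  ped_mean  ref_p5  ref_p95  inside_pi
   2    SPIR    0.0665  0.0450   0.1140       True
   2     CAN    0.6693  0.3191   1.2746       True
  17    SPIR    0.0986  0.0450   0.1140       True
  17     CAN    0.9481  0.3191   1.2746       True

{'cl': 11.7, 'clm1': 12.3, 'v2': 11.6, 'clm': 9.6, 'v4': 12.5, 'ka': 30.0}
```

Row 2 of the grid says a median 2-year-old girl (12.63 kg) has an apparent
SPIR clearance of 174 L/h versus 629 L/h in adults. The sweep says the mean
AUC (mg·h/L) of both analytes after 0.5 mg/kg lies inside the adult 5th–95th
prediction band after 25 mg, at both age extremes — the dose meets the
exposure-matching target. The last line gives the expected relative standard
error (%) of each estimated parameter under the 18-subject sparse design:
all below 35%, so the design is adequate for population re-estimation.

A CLI mirrors these steps (`spirped scale-pediatric`, `spirped dose-sweep`,
`spirped simulate-trial`, `spirped evaluate-design`, `spirped make-synthetic`,
`spirped simulate-adult`); every stochastic subcommand takes `--seed` and
writes CSVs with provenance headers.

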