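"""Synthetic stand-ins for the adult phase-I studies.

The adult model was built on rich-sampled single-dose data from 92 healthy
subjects (14 at 25 mg from a pilot bioavailability study, 78 at 100 mg from
the pivotal bioavailability and food-effect studies), plus a 23-subject
fed/fasted crossover arm.  The original concentration data are proprietary,
so this module generates datasets with the same statistical structure —
log-normal between-subject variability with the (cl, v2) covariance,
proportional residual error, and the demographic weight distribution — for
parameter-recovery experiments.  Subject weights are drawn for realism of the
covariate columns, but the adult model itself carries no weight effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CMT_CAN, CMT_DEPOT, CMT_SPIR, SEX_CODE
from .model import ADULT_TYPICAL, DoseEvent, PKParameterSet, ValidationError, solve_profile
from .population import (
    ADULT_VARIABILITY, VariabilitySpec, apply_residual, sample_individual,
)
from .scenarios import HEALTHY_FED, apply_scenario

#: Rich sampling grid (h) spanning absorption through the CAN terminal phase.
RICH_SAMPLING_TIMES = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0,
                       12.0, 24.0, 48.0, 72.0, 96.0, 120.0)

#: Adult weight distribution (kg) of the phase-I studies.
ADULT_WEIGHT_MEAN = 64.1
ADULT_WEIGHT_SD = 6.4
ADULT_WEIGHT_MIN = 40.0


@dataclass(frozen=True)
class StudyArm:
    n: int
    dose_mg: float
    fed: bool = False

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("arm size must be positive")
        if self.dose_mg <= 0:
            raise ValidationError("dose must be positive")


@dataclass(frozen=True)
class StudySpec:
    """Design of a synthetic rich-sampled adult study."""

    arms: tuple[StudyArm, ...] = (StudyArm(14, 25.0), StudyArm(78, 100.0))
    times: tuple[float, ...] = RICH_SAMPLING_TIMES
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("sampling times must be strictly increasing")


def draw_adult_weight(rng: np.random.Generator) -> float:
    """Normal weight draw truncated below at 40 kg (rejection sampling)."""
    while True:
        wt = rng.normal(ADULT_WEIGHT_MEAN, ADULT_WEIGHT_SD)
        if wt > ADULT_WEIGHT_MIN:
            return float(wt)


@dataclass
class TruthBundle:
    """A synthetic dataset plus the latent values that generated it."""

    dataset: pd.DataFrame
    typical: PKParameterSet
    variability: VariabilitySpec
    etas: pd.DataFrame          # one row per subject, columns = BSV params


def _subject_rows(sid: int, weight: float, age: float, sex: str,
                  params: PKParameterSet, doses: list[DoseEvent],
                  times, spec: VariabilitySpec, rng, residual: bool = True,
                  time_offset: float = 0.0) -> list[dict]:
    profile = solve_profile(params, doses, np.asarray(times, dtype=float))
    if residual:
        profile = apply_residual(profile, spec, rng)
    base = {"ID": sid, "WT": weight, "AGE": age, "SEX": SEX_CODE[sex]}
    rows = []
    for dose in doses:
        rows.append({**base, "TIME": dose.time + time_offset,
                     "AMT": dose.amount, "DV": np.nan, "CMT": CMT_DEPOT,
                     "EVID": 1, "MDV": 1})
    for t, spir, can in zip(profile.times, profile.spir_conc,
                            profile.can_conc):
        for cmt, dv in ((CMT_SPIR, spir), (CMT_CAN, can)):
            rows.append({**base, "TIME": float(t) + time_offset,
                         "AMT": np.nan, "DV": float(dv), "CMT": cmt,
                         "EVID": 0, "MDV": 0})
    return rows


_COLUMNS = ["ID", "TIME", "AMT", "DV", "CMT", "EVID", "MDV", "WT", "AGE", "SEX"]


def generate_adult_study(spec: StudySpec = StudySpec(),
                         typical: PKParameterSet = ADULT_TYPICAL,
                         variability: VariabilitySpec = ADULT_VARIABILITY,
                         rng: np.random.Generator | int | None = None,
                         ) -> pd.DataFrame:
    """Generate the default 92-subject rich single-dose adult dataset."""
    return generate_truth_bundle(spec, typical, variability, rng).dataset


def generate_truth_bundle(spec: StudySpec = StudySpec(),
                          typical: PKParameterSet = ADULT_TYPICAL,
                          variability: VariabilitySpec = ADULT_VARIABILITY,
                          rng: np.random.Generator | int | None = None,
                          ) -> TruthBundle:
    """Generate an adult study dataset along with its latent ground truth."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)
    rows: list[dict] = []
    eta_rows: list[dict] = []
    sid = 1
    for arm in spec.arms:
        arm_typical = (apply_scenario(typical, HEALTHY_FED) if arm.fed
                       else typical)
        for _ in range(arm.n):
            weight = draw_adult_weight(rng)
            params, eta = sample_individual(arm_typical, variability, rng)
            rows += _subject_rows(sid, weight, 30.0, "M", params,
                                  [DoseEvent(0.0, arm.dose_mg)], spec.times,
                                  variability, rng)
            eta_rows.append({"ID": sid, "dose_mg": arm.dose_mg,
                             "fed": arm.fed, **eta})
            sid += 1
    dataset = pd.DataFrame(rows, columns=_COLUMNS)
    return TruthBundle(dataset, typical, variability, pd.DataFrame(eta_rows))


def generate_fed_arm(n: int = 23, dose_mg: float = 100.0,
                     times=RICH_SAMPLING_TIMES,
                     typical: PKParameterSet = ADULT_TYPICAL,
                     variability: VariabilitySpec = ADULT_VARIABILITY,
                     rng: np.random.Generator | int = 0,
                     washout_h: float = 336.0) -> pd.DataFrame:
    """Crossover-style paired fasted/fed dataset for the food-effect study.

    Each subject keeps the same between-subject random effects in both
    periods; the fed period applies the food-effect scenario (reduced ka,
    doubled bioavailability, reduced fraction metabolized) and is offset by a
    washout so times stay non-decreasing within subject.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    fed_typical = apply_scenario(typical, HEALTHY_FED)
    rows: list[dict] = []
    for sid in range(1, n + 1):
        weight = draw_adult_weight(rng)
        fasted_params, eta = sample_individual(typical, variability, rng)
        eta_factors = {name: np.exp(e) for name, e in eta.items()}
        fed_params = fed_typical.with_updates(
            **{name: getattr(fed_typical, name) * f
               for name, f in eta_factors.items()})
        rows += _subject_rows(sid, weight, 30.0, "M", fasted_params,
                              [DoseEvent(0.0, dose_mg)], times,
                              variability, rng)
        rows += _subject_rows(sid, weight, 30.0, "M", fed_params,
                              [DoseEvent(0.0, dose_mg)], times,
                              variability, rng, time_offset=washout_h)
    return pd.DataFrame(rows, columns=_COLUMNS)
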