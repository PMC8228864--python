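"""Windowed sparse PK sampling design for the pediatric trial.

The single-dose pediatric study is split into three age groups (Group 1:
12 to <17 y, Group 2: 6 to <12 y, Group 3: 2 to <6 y).  Each group is
randomized 1:1 into two sampling subgroups whose day-1 windows interleave so
that, pooled, the absorption/early-distribution phase from 5 min to 8 h is
covered; every subject additionally contributes one sample in each of the two
late windows (46-50 h and 166-170 h).  Group 1 subjects give 6 samples each
(4 on day 1), Groups 2-3 give 5 (3 on day 1).  Within each window one sample
is drawn uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CAN, DoseEvent, SPIR, ValidationError, solve_profile
from .population import (
    ADULT_VARIABILITY, VariabilitySpec, VirtualSubject, apply_residual,
)

#: Late sampling windows shared by all groups (h post-dose).
LATE_WINDOWS = ((46.0, 50.0), (166.0, 170.0))

#: NONMEM compartment codes used in generated datasets.
CMT_DEPOT = 1
CMT_SPIR = 2
CMT_CAN = 4
CMT_TO_ANALYTE = {CMT_SPIR: SPIR, CMT_CAN: CAN}
SEX_CODE = {"F": 0, "M": 1}


@dataclass(frozen=True)
class SamplingScheme:
    """One subgroup's sampling windows."""

    group: int
    subgroup: str
    day1_windows: tuple[tuple[float, float], ...]
    late_windows: tuple[tuple[float, float], ...] = LATE_WINDOWS

    def __post_init__(self) -> None:
        if self.group not in (1, 2, 3):
            raise ValidationError("group must be 1, 2 or 3")
        expected_day1 = 4 if self.group == 1 else 3
        if len(self.day1_windows) != expected_day1:
            raise ValidationError(
                f"group {self.group} requires {expected_day1} day-1 windows")
        prev_end = -1.0
        for start, end in self.all_windows:
            if not (0 <= start < end):
                raise ValidationError("windows must satisfy 0 <= start < end")
            if start < prev_end:
                raise ValidationError("windows must be non-overlapping and increasing")
            prev_end = end

    @property
    def all_windows(self) -> tuple[tuple[float, float], ...]:
        return self.day1_windows + self.late_windows

    @property
    def samples_per_subject(self) -> int:
        return len(self.all_windows)


def builtin_schemes() -> dict[str, SamplingScheme]:
    """The six study sampling subgroups, keyed by subgroup id."""
    return {
        "1.1": SamplingScheme(1, "1.1",
                              ((0.08, 0.5), (1.0, 1.5), (2.0, 3.0), (4.0, 6.0))),
        "1.2": SamplingScheme(1, "1.2",
                              ((0.5, 1.0), (1.5, 2.0), (3.0, 4.0), (6.0, 8.0))),
        "2.1": SamplingScheme(2, "2.1",
                              ((0.08, 0.75), (1.5, 2.5), (3.5, 6.0))),
        "2.2": SamplingScheme(2, "2.2",
                              ((0.75, 1.5), (2.5, 3.5), (6.0, 8.0))),
        "3.1": SamplingScheme(3, "3.1",
                              ((0.08, 0.75), (1.5, 2.5), (3.5, 6.0))),
        "3.2": SamplingScheme(3, "3.2",
                              ((0.75, 1.5), (2.5, 3.5), (6.0, 8.0))),
    }


def age_to_group(age: float) -> int:
    """Map an age in years to its study group."""
    if 12 <= age < 17:
        return 1
    if 6 <= age < 12:
        return 2
    if 2 <= age < 6:
        return 3
    raise ValidationError(f"age {age} outside the study range [2, 17)")


def draw_sampling_times(scheme: SamplingScheme,
                        rng: np.random.Generator | int) -> np.ndarray:
    """One uniform draw per window, returned sorted."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    times = np.array([rng.uniform(start, end)
                      for start, end in scheme.all_windows])
    return np.sort(times)


def randomize_subgroups(subject_ids: list[int],
                        rng: np.random.Generator) -> dict[int, int]:
    """1:1 block randomization: exactly half of the ids to each subgroup."""
    n = len(subject_ids)
    if n % 2 != 0:
        raise ValidationError("1:1 randomization requires an even group size")
    order = list(subject_ids)
    rng.shuffle(order)
    return {sid: (1 if i < n // 2 else 2) for i, sid in enumerate(order)}


def simulate_sparse_study(cohort: list[VirtualSubject],
                          dose_mg_per_kg: float = 0.5,
                          schemes: dict[str, SamplingScheme] | None = None,
                          rng: np.random.Generator | int = 0,
                          spec: VariabilitySpec = ADULT_VARIABILITY,
                          residual: bool = True) -> pd.DataFrame:
    """Simulate the sparse pediatric study and return a NONMEM-style dataset.

    Each subject receives a single oral dose of ``dose_mg_per_kg * weight``
    at time 0, is randomized 1:1 to a sampling subgroup within their age
    group, and contributes both analytes at every drawn sampling time (a
    single blood draw assays both).  Proportional residual error is applied
    unless ``residual`` is False.
    """
    schemes = builtin_schemes() if schemes is None else schemes
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng

    by_group: dict[int, list[VirtualSubject]] = {}
    for subject in cohort:
        by_group.setdefault(age_to_group(subject.age), []).append(subject)

    rows = []
    for group in sorted(by_group):
        members = by_group[group]
        assignment = randomize_subgroups([s.id for s in members], rng)
        for subject in members:
            scheme = schemes[f"{group}.{assignment[subject.id]}"]
            times = draw_sampling_times(scheme, rng)
            amt = dose_mg_per_kg * subject.weight
            profile = solve_profile(subject.params,
                                    [DoseEvent(0.0, amt)], times)
            if residual:
                profile = apply_residual(profile, spec, rng)
            base = {"ID": subject.id, "WT": subject.weight,
                    "AGE": subject.age, "SEX": SEX_CODE[subject.sex]}
            rows.append({**base, "TIME": 0.0, "AMT": amt, "DV": np.nan,
                         "CMT": CMT_DEPOT, "EVID": 1, "MDV": 1})
            for t, spir, can in zip(times, profile.spir_conc,
                                    profile.can_conc):
                for cmt, dv in ((CMT_SPIR, spir), (CMT_CAN, can)):
                    rows.append({**base, "TIME": float(t), "AMT": np.nan,
                                 "DV": float(dv), "CMT": cmt, "EVID": 0,
                                 "MDV": 0})
    columns = ["ID", "TIME", "AMT", "DV", "CMT", "EVID", "MDV",
               "WT", "AGE", "SEX"]
    return pd.DataFrame(rows, columns=columns)
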