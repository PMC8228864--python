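"""Allometric bridging of adult PK parameters to pediatric body weights.

Pediatric typical values follow the fixed-exponent power law
``P_ped = P_adult * (WT / 70)^b`` with b = 0.75 for elimination and
intercompartmental clearances, b = 1 for volumes of distribution, and b = 0
(no scaling) for ka, the absorption lag and the fraction metabolized.  The
approach assumes the drug-metabolizing enzymes are mature from age 2, so
weight is the only driver of the adult-to-child difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import (
    ADULT_TYPICAL, CLEARANCE_PARAMS, PKParameterSet, UNSCALED_PARAMS,
    ValidationError, VOLUME_PARAMS,
)


@dataclass(frozen=True)
class AllometricRule:
    """Exponents and reference weight of the power-law scaling."""

    exponent_clearance: float = 0.75
    exponent_volume: float = 1.0
    reference_weight: float = 70.0

    def __post_init__(self) -> None:
        if self.reference_weight <= 0:
            raise ValidationError("reference_weight must be positive")


DEFAULT_RULE = AllometricRule()

#: Reference ages (years) used for pediatric dose evaluation.
REFERENCE_AGES = (2, 6, 12, 17)


@dataclass
class WeightTable:
    """Median body weight (kg) by (age in years, sex)."""

    weights: dict[tuple[float, str], float]

    def __post_init__(self) -> None:
        for (age, sex), wt in self.weights.items():
            if wt <= 0:
                raise ValidationError("weights must be positive")
            if age < 2:
                raise ValidationError("weight table covers ages >= 2 only")
            if sex not in ("F", "M"):
                raise ValidationError("sex must be 'F' or 'M'")

    def lookup(self, age: float, sex: str) -> float:
        try:
            return self.weights[(age, sex)]
        except KeyError:
            raise ValidationError(
                f"no weight for age {age}, sex {sex!r}") from None

    @classmethod
    def from_csv(cls, path) -> "WeightTable":
        df = pd.read_csv(path, comment="#")
        return cls({(float(r.age_years), str(r.sex)): float(r.weight_kg)
                    for r in df.itertuples()})

    def to_csv(self, path) -> None:
        rows = [{"age_years": a, "sex": s, "weight_kg": w}
                for (a, s), w in sorted(self.weights.items())]
        pd.DataFrame(rows).to_csv(path, index=False)


def implied_weight(v2_ped: float, v2_adult: float = ADULT_TYPICAL.v2,
                   rule: AllometricRule = DEFAULT_RULE) -> float:
    """Invert the exponent-1 volume rule: weight = 70 * V2_ped / V2_adult.

    Recovers the growth-chart median weight behind a scaled central volume,
    which makes a published pediatric parameter grid self-reproducing without
    access to the original growth-chart lookups.
    """
    if v2_ped <= 0 or v2_adult <= 0:
        raise ValidationError("volumes must be positive")
    return rule.reference_weight * v2_ped / v2_adult


#: Pediatric central volumes by (age, sex) from the published extrapolation;
#: used only to derive the default median weights below.
_PEDIATRIC_V2 = {
    (2, "F"): 93.28, (2, "M"): 87.00,
    (6, "F"): 159.46, (6, "M"): 158.65,
    (12, "F"): 315.00, (12, "M"): 320.47,
    (17, "F"): 474.09, (17, "M"): 404.07,
}

#: Default growth-chart median weights for the eight reference age/sex cells,
#: recovered by inverting the volume scaling (approx. 12.63, 11.78, 21.59,
#: 21.48, 42.65, 43.39, 64.19, 54.71 kg).
DEFAULT_WEIGHTS = WeightTable({
    cell: implied_weight(v2) for cell, v2 in _PEDIATRIC_V2.items()
})


def scale_parameters(adult: PKParameterSet, weight: float,
                     rule: AllometricRule = DEFAULT_RULE) -> PKParameterSet:
    """Scale an adult typical parameter set to a body weight.

    Clearances (cl, clm1, clm, q, q1) scale with exponent 0.75, volumes
    (v2, v3, v4, v5) with exponent 1; ka, alag1 and fm are unchanged.
    """
    if weight <= 0:
        raise ValidationError("weight must be positive")
    ratio = weight / rule.reference_weight
    f_cl = ratio ** rule.exponent_clearance
    f_v = ratio ** rule.exponent_volume
    updates = {name: getattr(adult, name) * f_cl for name in CLEARANCE_PARAMS}
    updates.update({name: getattr(adult, name) * f_v for name in VOLUME_PARAMS})
    return adult.with_updates(**updates)


def rebuild_pediatric_table(adult: PKParameterSet = ADULT_TYPICAL,
                            weights: WeightTable = DEFAULT_WEIGHTS,
                            rule: AllometricRule = DEFAULT_RULE,
                            ) -> pd.DataFrame:
    """Build the full pediatric typical-parameter grid by age and sex.

    Returns one row per (age, sex) cell of ``weights`` plus the adult
    reference row, with all twelve structural parameters as columns.
    """
    rows = []
    adult_row = {"age": "adult", "sex": "-",
                 "weight_kg": rule.reference_weight, **adult.as_dict()}
    rows.append(adult_row)
    for (age, sex), wt in sorted(weights.weights.items()):
        scaled = scale_parameters(adult, wt, rule)
        rows.append({"age": age, "sex": sex, "weight_kg": wt,
                     **scaled.as_dict()})
    return pd.DataFrame(rows)
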