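"""Fisher-information design evaluation and the pooled population estimator."""

import math

import numpy as np
import pandas as pd
import pytest
import sympy

from spirped import (
    ADULT_TYPICAL, ADULT_VARIABILITY, SubjectDesign, ValidationError,
    VariabilitySpec, build_cohort, evaluate_design, expected_rse_fim,
    fit_pooled, generate_adult_study, reference_sparse_design,
    simulate_sparse_study,
)
from spirped.synthetic import StudyArm, StudySpec

EPS_ONLY = VariabilitySpec(omega2={}, eps1=0.08, eps2=0.017)


def toy_params():
    """One-compartment parent and metabolite (q = q1 = 0, fm = 1)."""
    return ADULT_TYPICAL.with_updates(q=0.0, q1=0.0, fm=1.0)


def analytic_toy_fim(design, params, estimated, eps1, eps2):
    """Independent symbolic-derivative FIM for the one-compartment toy.

    Closed-form parent (Bateman) and metabolite (three-exponential)
    concentrations are differentiated with sympy; the information matrix is
    assembled from scratch with diagonal proportional-error variance.
    """
    clm1, v2, ka, clm, v4, t, dose = sympy.symbols(
        "clm1 v2 ka clm v4 t dose", positive=True)
    k2 = clm1 / v2
    k4 = clm / v4
    tau = t - params.alag1
    a2 = dose * ka / (ka - k2) * (sympy.exp(-k2 * tau) - sympy.exp(-ka * tau))
    a4 = dose * k2 * ka * (
        sympy.exp(-k2 * tau) / ((ka - k2) * (k4 - k2))
        + sympy.exp(-ka * tau) / ((k2 - ka) * (k4 - ka))
        + sympy.exp(-k4 * tau) / ((k2 - k4) * (ka - k4)))
    exprs = {"SPIR": a2 / v2, "CAN": a4 / v4}
    symbols = {"clm1": clm1, "v2": v2, "ka": ka, "clm": clm, "v4": v4}
    subs0 = {clm1: params.clm1, v2: params.v2, ka: params.ka,
             clm: params.clm, v4: params.v4}
    fim = np.zeros((len(estimated), len(estimated)))
    for subject in design:
        for analyte, sigma2 in (("SPIR", eps1), ("CAN", eps2)):
            expr = exprs[analyte]
            grads = [sympy.diff(expr, symbols[name]) for name in estimated]
            for tt in subject.times:
                at = dict(subs0)
                at[t] = tt
                at[dose] = subject.dose_mg
                f = float(expr.subs(at))
                j = np.array([float(g.subs(at)) for g in grads])
                fim += np.outer(j, j) / (sigma2 * f * f)
    cov = np.linalg.inv(fim)
    return {name: 100.0 * math.sqrt(cov[k, k])
            / getattr(params, name) for k, name in enumerate(estimated)}


class TestExpectedRseFim:
    def test_matches_symbolic_oracle_on_toy_model(self):
        params = toy_params()
        design = [SubjectDesign(70.0, 100.0, (0.5, 2.0, 8.0, 24.0)),
                  SubjectDesign(70.0, 100.0, (1.0, 4.0, 12.0, 48.0))]
        estimated = ("clm1", "v2", "ka", "clm", "v4")
        result = expected_rse_fim(design, typical=params, spec=EPS_ONLY,
                                  estimated=estimated)
        oracle = analytic_toy_fim(design, params, estimated, 0.08, 0.017)
        for name in estimated:
            assert result.rse[name] == pytest.approx(oracle[name], rel=1e-6)

    def test_information_additivity(self):
        design = reference_sparse_design(rng=5)
        single = expected_rse_fim(design)
        doubled = expected_rse_fim(design + design)
        for name, value in single.rse.items():
            assert doubled.rse[name] == pytest.approx(value / math.sqrt(2),
                                                      rel=1e-9)

    def test_extra_window_never_loses_information(self):
        design = reference_sparse_design(rng=5)
        base = expected_rse_fim(design)
        richer = [SubjectDesign(s.weight, s.dose_mg,
                                tuple(sorted(s.times + (30.0,))))
                  for s in design]
        more = expected_rse_fim(richer)
        for name, value in base.rse.items():
            assert more.rse[name] <= value + 1e-9

    def test_unidentifiable_direction_raises(self):
        # with fm = 1 the non-metabolic clearance cl drops out of the model
        params = toy_params()
        design = [SubjectDesign(70.0, 100.0, (1.0, 4.0, 12.0, 48.0))]
        with pytest.raises(ValidationError):
            expected_rse_fim(design, typical=params, spec=EPS_ONLY,
                             estimated=("cl", "v2", "ka"))


class TestFitPooled:
    def test_zero_noise_rich_fit_recovers_truth(self):
        spec0 = ADULT_VARIABILITY.without_variability()
        data = generate_adult_study(
            StudySpec(arms=(StudyArm(3, 25.0), StudyArm(3, 100.0)), seed=0),
            variability=spec0)
        init = ADULT_TYPICAL.with_updates(cl=500.0, v2=400.0, clm=25.0,
                                          ka=3.0, clm1=300.0, v4=120.0)
        fit = fit_pooled(data, init=init, allometric=False,
                         truth=ADULT_TYPICAL)
        assert fit.converged
        assert max(abs(b) for b in fit.pct_bias.values()) < 0.1

    def test_zero_noise_sparse_allometric_fit(self):
        """The allometric tie maps sparse pediatric data back to adults."""
        spec0 = ADULT_VARIABILITY.without_variability()
        cohort = build_cohort(3, ages=[2, 6, 12], spec=spec0, rng=1)
        study = simulate_sparse_study(cohort, 0.5, rng=1, spec=spec0,
                                      residual=False)
        init = ADULT_TYPICAL.with_updates(cl=800.0, v2=300.0, ka=8.0)
        fit = fit_pooled(study, init=init, truth=ADULT_TYPICAL)
        assert max(abs(b) for b in fit.pct_bias.values()) < 0.1

    def test_insufficient_observations_rejected(self):
        spec0 = ADULT_VARIABILITY.without_variability()
        data = generate_adult_study(
            StudySpec(arms=(StudyArm(1, 25.0),), times=(1.0,), seed=0),
            variability=spec0)
        with pytest.raises(ValidationError):
            fit_pooled(data, allometric=False)


class TestEvaluateDesign:
    def test_zero_variability_zero_rse(self):
        spec0 = ADULT_VARIABILITY.without_variability()
        ev = evaluate_design(n_replicates=3, spec=spec0, rng=0,
                             residual=False)
        assert ev.convergence_fraction == 1.0
        assert all(v < 1e-6 for v in ev.rse.values())

    def test_seeded_determinism(self):
        a = evaluate_design(n_replicates=3, rng=77)
        b = evaluate_design(n_replicates=3, rng=77)
        pd.testing.assert_frame_equal(a.estimates, b.estimates)
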