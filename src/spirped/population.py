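"""Between-subject variability (BSV) sampling and residual error.

Individual parameters follow the exponential model ``P_i = P_typ * exp(eta_i)``
with log-scale random effects ``eta``.  Nine structural parameters carry BSV
(ka, cl, v2, q, clm1, clm, v4, q1, v5); the (cl, v2) pair is drawn jointly
with a covariance term, all others independently.  Residual error is
proportional per analyte: ``obs = pred * (1 + eps)``, ``eps ~ N(0, sigma^2)``.
The adult variance estimates are carried unchanged to pediatric simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    ADULT_TYPICAL, ConcentrationProfile, PKParameterSet, ValidationError,
    SPIR, CAN, logger,
)

#: Parameters with a between-subject variance, in sampling order.
BSV_PARAMS = ("ka", "cl", "v2", "q", "clm1", "clm", "v4", "q1", "v5")


@dataclass(frozen=True)
class VariabilitySpec:
    """Log-normal BSV variances (omega^2) and proportional residual variances.

    ``omega2`` maps parameter name to the variance of its log-scale random
    effect; ``cov_cl_v2`` is the covariance between the cl and v2 effects.
    ``eps1``/``eps2`` are the proportional residual variances for SPIR and
    CAN (NONMEM SIGMA convention: variances, not SDs).
    """

    omega2: dict[str, float]
    cov_cl_v2: float = 0.0
    eps1: float = 0.0
    eps2: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.omega2.items():
            if name not in BSV_PARAMS:
                raise ValidationError(f"no BSV is defined for parameter {name!r}")
            if value < 0:
                raise ValidationError(f"omega2[{name!r}] must be non-negative")
        if self.eps1 < 0 or self.eps2 < 0:
            raise ValidationError("residual variances must be non-negative")
        w_cl = self.omega2.get("cl", 0.0)
        w_v2 = self.omega2.get("v2", 0.0)
        if self.cov_cl_v2 ** 2 > w_cl * w_v2 * (1 + 1e-12):
            raise ValidationError(
                "(cl, v2) covariance block is not positive semidefinite")

    def omega(self, name: str) -> float:
        return self.omega2.get(name, 0.0)

    def eps(self, analyte: str) -> float:
        return {SPIR: self.eps1, CAN: self.eps2}[analyte]

    def omega_matrix(self) -> np.ndarray:
        """Full BSV covariance matrix over :data:`BSV_PARAMS`."""
        cov = np.diag([self.omega(p) for p in BSV_PARAMS])
        i, j = BSV_PARAMS.index("cl"), BSV_PARAMS.index("v2")
        cov[i, j] = cov[j, i] = self.cov_cl_v2
        return cov

    def without_variability(self) -> "VariabilitySpec":
        return VariabilitySpec({p: 0.0 for p in self.omega2}, 0.0, 0.0, 0.0)


#: Adult BSV and residual-error estimates carried over to pediatrics.
ADULT_VARIABILITY = VariabilitySpec(
    omega2={"ka": 0.9, "cl": 0.166, "v2": 0.118, "q": 0.08, "clm1": 0.18,
            "clm": 0.08, "v4": 0.03, "q1": 0.07, "v5": 0.09},
    cov_cl_v2=0.112,
    eps1=0.08,
    eps2=0.017,
)


@dataclass
class VirtualSubject:
    """A simulated study participant with individual PK parameters."""

    id: int
    age: float
    sex: str
    weight: float
    params: PKParameterSet
    eta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValidationError("weight must be positive")
        if self.sex not in ("F", "M"):
            raise ValidationError("sex must be 'F' or 'M'")


def require_pediatric_age(age: float) -> None:
    """Enforce the pediatric bracket of the bridging model.

    The study population is 2 to <17 years; age 17 itself is additionally
    accepted because it serves as the oldest reference age for dose
    evaluation.
    """
    if not (2.0 <= age <= 17.0):
        raise ValidationError(
            f"age {age} outside the supported pediatric range [2, 17]")


def draw_etas(spec: VariabilitySpec, rng: np.random.Generator,
              n: int = 1) -> np.ndarray:
    """Draw ``n`` random-effect vectors over :data:`BSV_PARAMS`.

    (eta_cl, eta_v2) are sampled jointly through the Cholesky factor of their
    2x2 covariance block; all other effects are independent normals.  An
    exactly singular block receives a 1e-12 jitter (with a warning) so the
    factorization is always defined.
    """
    etas = np.zeros((n, len(BSV_PARAMS)))
    i_cl, i_v2 = BSV_PARAMS.index("cl"), BSV_PARAMS.index("v2")
    block = np.array([[spec.omega("cl"), spec.cov_cl_v2],
                      [spec.cov_cl_v2, spec.omega("v2")]])
    if np.any(np.diag(block) > 0):
        det = block[0, 0] * block[1, 1] - block[0, 1] ** 2
        if det <= 0 and spec.cov_cl_v2 != 0:
            logger.warning("(cl, v2) covariance block singular; adding 1e-12 jitter")
            block = block + 1e-12 * np.eye(2)
        chol = np.linalg.cholesky(block + 1e-300 * np.eye(2))
        z = rng.standard_normal((n, 2))
        joint = z @ chol.T
        etas[:, i_cl] = joint[:, 0]
        etas[:, i_v2] = joint[:, 1]
    for k, name in enumerate(BSV_PARAMS):
        if k in (i_cl, i_v2):
            continue
        w = spec.omega(name)
        etas[:, k] = rng.standard_normal(n) * np.sqrt(w) if w > 0 else 0.0
    return etas


def sample_individual(typical: PKParameterSet, spec: VariabilitySpec,
                      rng: np.random.Generator | int,
                      ) -> tuple[PKParameterSet, dict[str, float]]:
    """Sample one individual parameter set ``P_i = P_typ * exp(eta_i)``.

    Returns the individual set together with the latent ``eta`` values.
    Parameters without a BSV term (alag1, fm, v3) stay at their typical value.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    eta = draw_etas(spec, rng, n=1)[0]
    updates = {name: getattr(typical, name) * float(np.exp(e))
               for name, e in zip(BSV_PARAMS, eta)}
    individual = typical.with_updates(**updates)
    return individual, dict(zip(BSV_PARAMS, eta))


def apply_residual(profile: ConcentrationProfile, spec: VariabilitySpec,
                   rng: np.random.Generator | int) -> ConcentrationProfile:
    """Overlay proportional residual error on a predicted profile.

    ``obs = pred * (1 + eps)`` with analyte-specific variance; draws that
    would produce a negative observation are floored at zero and counted in
    the log.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n = len(profile.times)
    floored = 0
    observed = {}
    for analyte, pred in ((SPIR, profile.spir_conc), (CAN, profile.can_conc)):
        sigma = np.sqrt(spec.eps(analyte))
        obs = pred * (1.0 + rng.standard_normal(n) * sigma)
        floored += int(np.sum(obs < 0))
        observed[analyte] = np.maximum(obs, 0.0)
    if floored:
        logger.info("apply_residual: floored %d negative observations at 0", floored)
    return ConcentrationProfile(profile.times.copy(),
                                observed[SPIR], observed[CAN])


def build_cohort(n_per_sex: int, ages, weight_source=None,
                 rng: np.random.Generator | int = 0,
                 typical_adult: PKParameterSet = ADULT_TYPICAL,
                 spec: VariabilitySpec = ADULT_VARIABILITY,
                 scenario=None) -> list[VirtualSubject]:
    """Build a virtual pediatric cohort of ``n_per_sex`` subjects per age/sex.

    Weights come from ``weight_source`` (a :class:`spirped.allometry.WeightTable`;
    defaults to the built-in growth-chart medians), adult typical values are
    allometrically scaled to each weight, an optional scenario is applied, and
    each subject then receives an individual BSV draw.
    """
    from .allometry import DEFAULT_WEIGHTS, scale_parameters
    from .scenarios import apply_scenario

    if n_per_sex <= 0:
        raise ValidationError("n_per_sex must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    weights = weight_source if weight_source is not None else DEFAULT_WEIGHTS
    subjects: list[VirtualSubject] = []
    sid = 1
    for age in ages:
        require_pediatric_age(age)
        for sex in ("F", "M"):
            wt = weights.lookup(age, sex)
            typ = scale_parameters(typical_adult, wt)
            if scenario is not None:
                typ = apply_scenario(typ, scenario)
            for _ in range(n_per_sex):
                params, eta = sample_individual(typ, spec, rng)
                subjects.append(VirtualSubject(sid, float(age), sex, wt,
                                               params, eta))
                sid += 1
    return subjects
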