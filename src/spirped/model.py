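"""Parent-metabolite structural PK model for spironolactone (SPIR) and canrenone (CAN).

The structural model is a linear five-state compartmental system: an oral
depot with first-order absorption (``ka``) and an absorption lag, a
two-compartment disposition model for the parent SPIR (central ``v2``,
peripheral ``v3``), and a two-compartment disposition model for the active
metabolite CAN (central ``v4``, peripheral ``v5``).  A fixed fraction ``fm``
of the parent's metabolic clearance ``clm1`` is routed to CAN formation, so
the total apparent clearance of SPIR is

    CL_tot = cl * (1 - fm) + clm1 * fm

and the CAN formation flux is ``fm * clm1`` times the SPIR central
concentration.  All clearances and volumes are apparent (conditioned on the
unknown oral bioavailability F); without IV data only ratios to F are
identifiable.  Internal units are mg, L and h, so concentrations are mg/L.

Because the system is linear and time-invariant, a dosing history of oral
boluses is solved exactly by superposition of matrix-exponential impulse
responses; an eigendecomposition is used for speed, with a segment-wise
``expm`` propagation as fallback for (nearly) defective rate matrices, and a
stiff ODE integration path retained for cross-checking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.integrate import solve_ivp

logger = logging.getLogger("spirped")

#: Analyte labels used throughout the package.
SPIR = "SPIR"
CAN = "CAN"
ANALYTES = (SPIR, CAN)

#: Names of the structural parameters, in canonical order.
PARAM_NAMES = (
    "cl", "clm1", "v2", "q", "v3", "ka",
    "alag1", "fm", "clm", "v4", "q1", "v5",
)

#: Parameters that behave as clearances (allometric exponent 0.75).
CLEARANCE_PARAMS = ("cl", "clm1", "clm", "q", "q1")
#: Parameters that behave as volumes (allometric exponent 1).
VOLUME_PARAMS = ("v2", "v3", "v4", "v5")
#: Parameters left unscaled by body weight.
UNSCALED_PARAMS = ("ka", "alag1", "fm")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class PKParameterSet:
    """Apparent structural parameters of the SPIR/CAN model.

    Parameters
    ----------
    cl : float
        SPIR apparent clearance not routed to CAN, L/h.
    clm1 : float
        SPIR apparent metabolic clearance to CAN, L/h.
    v2, v3 : float
        SPIR central and peripheral volumes, L.
    q : float
        SPIR intercompartmental clearance, L/h.
    ka : float
        First-order absorption rate constant, 1/h.
    alag1 : float
        Absorption lag time, h.
    fm : float
        Fraction of parent clearance routed to CAN formation (0 < fm <= 1).
    clm : float
        CAN apparent clearance, L/h.
    v4, v5 : float
        CAN central and peripheral volumes, L.
    q1 : float
        CAN intercompartmental clearance, L/h.
    dose_scale : float
        Bioavailability multiplier "f" applied to every dose amount entering
        the depot; carries e.g. the fed-state doubling of bioavailability.
    scenario : str or None
        Tag recording a scenario already applied to this set (guards against
        silently compounding the same modifiers twice).
    """

    cl: float
    clm1: float
    v2: float
    q: float
    v3: float
    ka: float
    alag1: float
    fm: float
    clm: float
    v4: float
    q1: float
    v5: float
    dose_scale: float = 1.0
    scenario: str | None = None

    def __post_init__(self) -> None:
        for name in ("cl", "clm1", "v2", "v3", "ka", "clm", "v4", "v5"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        for name in ("q", "q1"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.alag1 < 0:
            raise ValidationError("alag1 must be non-negative")
        if not 0 < self.fm <= 1:
            raise ValidationError("fm must lie in (0, 1]")
        if not self.dose_scale > 0:
            raise ValidationError("dose_scale must be strictly positive")

    def with_updates(self, **kwargs: float) -> "PKParameterSet":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


#: Final adult population PK estimates for the spironolactone oral suspension
#: (apparent values, F-conditioned), from the adult model build on 92 healthy
#: subjects dosed 25 or 100 mg.
ADULT_TYPICAL = PKParameterSet(
    cl=629.0, clm1=217.0, v2=517.0, q=89.9, v3=777.0,
    ka=5.22, alag1=0.156, fm=0.7,
    clm=17.0, v4=189.0, q1=60.0, v5=448.0,
)


@dataclass(frozen=True)
class DoseEvent:
    """An oral bolus into the absorption depot.

    ``amount`` is in mg, or mg/kg when ``per_kg`` is set (resolved against a
    subject's body weight before simulation).
    """

    time: float
    amount: float
    per_kg: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError("dose time must be non-negative")
        if not self.amount > 0:
            raise ValidationError("dose amount must be strictly positive")

    def resolve(self, weight: float | None = None) -> "DoseEvent":
        """Return an absolute-mg dose, multiplying by ``weight`` if per-kg."""
        if not self.per_kg:
            return self
        if weight is None or weight <= 0:
            raise ValidationError("per-kg dose requires a positive body weight")
        return DoseEvent(self.time, self.amount * weight, per_kg=False)


@dataclass
class ConcentrationProfile:
    """Predicted or observed SPIR/CAN concentrations on a common time grid."""

    times: np.ndarray
    spir_conc: np.ndarray
    can_conc: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.spir_conc = np.asarray(self.spir_conc, dtype=float)
        self.can_conc = np.asarray(self.can_conc, dtype=float)
        if not (len(self.times) == len(self.spir_conc) == len(self.can_conc)):
            raise ValidationError("profile arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("time grid must be strictly increasing")
        if np.any(self.spir_conc < 0) or np.any(self.can_conc < 0):
            raise ValidationError("concentrations must be non-negative")

    def conc(self, analyte: str) -> np.ndarray:
        if analyte == SPIR:
            return self.spir_conc
        if analyte == CAN:
            return self.can_conc
        raise ValidationError(f"unknown analyte {analyte!r}")


def total_clearance(params: PKParameterSet) -> float:
    """Total apparent SPIR clearance, ``cl*(1-fm) + clm1*fm`` (L/h)."""
    return params.cl * (1.0 - params.fm) + params.clm1 * params.fm


def rate_matrix(params: PKParameterSet) -> np.ndarray:
    """First-order rate matrix of the five-state system (amount units).

    State order: depot, SPIR central, SPIR peripheral, CAN central,
    CAN peripheral.
    """
    p = params
    k20 = total_clearance(p) / p.v2        # total loss from SPIR central
    k23 = p.q / p.v2
    k32 = p.q / p.v3
    k24 = p.fm * p.clm1 / p.v2             # part of k20 routed to CAN
    k40 = p.clm / p.v4
    k45 = p.q1 / p.v4
    k54 = p.q1 / p.v5
    return np.array([
        [-p.ka, 0.0, 0.0, 0.0, 0.0],
        [p.ka, -(k20 + k23), k32, 0.0, 0.0],
        [0.0, k23, -k32, 0.0, 0.0],
        [0.0, k24, 0.0, -(k40 + k45), k54],
        [0.0, 0.0, 0.0, k45, -k54],
    ])


def _impulse_response_factors(A: np.ndarray):
    """Eigen-factorization of the unit depot impulse response.

    Returns ``(lam, c2, c4)`` such that the SPIR- and CAN-central amounts at
    elapsed time ``dt`` after a unit depot bolus are ``Re(c2 @ exp(lam*dt))``
    and ``Re(c4 @ exp(lam*dt))``.  Returns None when the eigenbasis is too
    ill-conditioned to trust (near-defective matrix).
    """
    lam, V = np.linalg.eig(A)
    try:
        w = np.linalg.solve(V, np.array([1.0, 0.0, 0.0, 0.0, 0.0]))
    except np.linalg.LinAlgError:
        return None
    if np.linalg.cond(V) > 1e10:
        return None
    return lam, V[1, :] * w, V[3, :] * w


def _solve_amounts_expm(A: np.ndarray, dose_times: np.ndarray,
                        dose_amts: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Segment-wise matrix-exponential propagation (robust fallback)."""
    events = sorted(set(dose_times) | set(times))
    state = np.zeros(5)
    t_prev = events[0] if events and events[0] < 0 else 0.0
    out = np.zeros((len(times), 5))
    t_index = {t: i for i, t in enumerate(times)}
    cache: dict[float, np.ndarray] = {}
    for t in events:
        dt = t - t_prev
        if dt > 0:
            P = cache.get(dt)
            if P is None:
                P = expm(A * dt)
                cache[dt] = P
            state = P @ state
        for td, amt in zip(dose_times, dose_amts):
            if td == t:
                state = state + np.array([amt, 0.0, 0.0, 0.0, 0.0])
        if t in t_index:
            out[t_index[t]] = state
        t_prev = t
    return out


def solve_profile(params: PKParameterSet, doses: Iterable[DoseEvent],
                  times: Sequence[float], weight: float | None = None,
                  ) -> ConcentrationProfile:
    """Solve the structural model for a dosing history on a time grid.

    Each dose enters the depot at ``time + alag1`` (the lag is an exact time
    shift of the input, matching NONMEM ALAG semantics) with an effective
    amount ``amount * dose_scale``.  Concentrations are the central-compartment
    amounts divided by ``v2`` (SPIR) and ``v4`` (CAN), in mg/L.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValidationError("time grid must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("time grid must be strictly increasing")
    if times[0] < 0:
        raise ValidationError("times must be non-negative")

    doses = [d.resolve(weight) for d in doses]
    if not doses:
        z = np.zeros_like(times)
        return ConcentrationProfile(times, z, z.copy())
    dose_times = np.array([d.time + params.alag1 for d in doses])
    dose_amts = np.array([d.amount * params.dose_scale for d in doses])

    A = rate_matrix(params)
    factors = _impulse_response_factors(A)
    if factors is not None:
        lam, c2, c4 = factors
        a2 = np.zeros(len(times))
        a4 = np.zeros(len(times))
        for td, amt in zip(dose_times, dose_amts):
            dt = times - td
            mask = dt >= 0
            if not np.any(mask):
                continue
            E = np.exp(np.outer(lam, dt[mask]))
            a2[mask] += amt * np.real(c2 @ E)
            a4[mask] += amt * np.real(c4 @ E)
    else:  # pragma: no cover - exercised only for near-defective systems
        amounts = _solve_amounts_expm(A, dose_times, dose_amts, times)
        a2, a4 = amounts[:, 1], amounts[:, 3]

    spir = np.maximum(a2, 0.0) / params.v2
    can = np.maximum(a4, 0.0) / params.v4
    return ConcentrationProfile(times, spir, can)


def solve_profile_ode(params: PKParameterSet, doses: Iterable[DoseEvent],
                      times: Sequence[float], weight: float | None = None,
                      rtol: float = 1e-10, atol: float = 1e-14,
                      ) -> ConcentrationProfile:
    """Stiff ODE integration of the same system (cross-check path).

    Slower than :func:`solve_profile`; used to validate the matrix-exponential
    solution and available for scenario experiments.
    """
    times = np.asarray(times, dtype=float)
    doses = [d.resolve(weight) for d in doses]
    events = sorted((d.time + params.alag1, d.amount * params.dose_scale)
                    for d in doses)
    A = rate_matrix(params)

    boundaries = sorted({0.0, float(times[-1])} | {t for t, _ in events})
    state = np.zeros(5)
    out = np.zeros((len(times), 5))
    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        for td, amt in events:
            if td == t0:
                state[0] += amt
        # grid times inside (t0, t1]; a bolus adds depot amount only, so
        # sampling exactly at a dose time is insensitive to the ordering
        sel = (times > t0) & (times <= t1)
        t_eval = np.unique(np.concatenate([times[sel], [t1]]))
        sol = solve_ivp(lambda t, y: A @ y, (t0, t1), state,
                        t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol)
        pos = {t: i for i, t in enumerate(sol.t)}
        for idx in np.where(sel)[0]:
            out[idx] = sol.y[:, pos[times[idx]]]
        state = sol.y[:, -1]
    for td, amt in events:  # doses at/after the last boundary
        if td == boundaries[-1]:
            state[0] += amt
    out[times <= boundaries[0]] = 0.0
    spir = np.maximum(out[:, 1], 0.0) / params.v2
    can = np.maximum(out[:, 3], 0.0) / params.v4
    return ConcentrationProfile(times, spir, can)


def _two_compartment_eigenvalues(cl_total: float, v_c: float, q: float,
                                 v_p: float) -> np.ndarray:
    """Disposition eigenvalue magnitudes of a two-compartment block."""
    k10 = cl_total / v_c
    k12 = q / v_c
    k21 = q / v_p
    s = k10 + k12 + k21
    p = k10 * k21
    if p <= 0:  # q == 0 collapses to a single exponential
        return np.array([k10])
    disc = math.sqrt(max(s * s - 4.0 * p, 0.0))
    return np.array([(s + disc) / 2.0, (s - disc) / 2.0])


def terminal_slope(params: PKParameterSet, analyte: str = SPIR,
                   include_depot: bool = True) -> float:
    """Terminal log-linear slope lambda_z (1/h) for one analyte.

    The slope is the smallest-magnitude non-zero rate among the exponentials
    feeding that analyte: the parent's disposition eigenvalues (plus ``ka``
    when ``include_depot``), and for the metabolite additionally its own
    disposition eigenvalues.  When absorption is slower than disposition the
    returned slope is ``ka`` (flip-flop kinetics).  Half-life is
    ``ln 2 / terminal_slope``.
    """
    spir_lams = _two_compartment_eigenvalues(
        total_clearance(params), params.v2, params.q, params.v3)
    if analyte == SPIR:
        candidates = list(spir_lams)
    elif analyte == CAN:
        can_lams = _two_compartment_eigenvalues(
            params.clm, params.v4, params.q1, params.v5)
        candidates = list(spir_lams) + list(can_lams)
    else:
        raise ValidationError(f"unknown analyte {analyte!r}")
    if include_depot:
        candidates.append(params.ka)
    candidates = [lam for lam in candidates if lam > 1e-12]
    if not candidates:
        raise ValidationError("degenerate system: no non-zero disposition rate")
    return min(candidates)


def half_life(params: PKParameterSet, analyte: str = SPIR,
              include_depot: bool = True) -> float:
    """Terminal half-life ``ln 2 / lambda_z`` in hours."""
    return math.log(2.0) / terminal_slope(params, analyte, include_depot)


def mg_per_l_to_ng_per_ml(conc_mg_per_l: np.ndarray | float):
    """Display conversion: 1 mg/L = 1000 ng/mL."""
    return np.asarray(conc_mg_per_l) * 1000.0
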