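"""Probability building blocks for bounded joint-damage counting processes.

Damage accrual in a joint area is modelled through negative binomial (NB)
increments between clinic visits, right-truncated to the number of joints in
the area that are still undamaged.  The NB mean over an interval is a
log-linear intensity in the attained damage counts of all areas (the dynamic
covariates) and any further configured covariates; a separate truncated NB
describes damage accumulated between arthritis onset and clinic entry.

All probability mass functions are evaluated on the log scale with log-gamma
functions, and truncation constants by log-sum-exp, so that large capacities
and small dispersions do not overflow.  A dispersion of exactly zero selects
the Poisson limit as its own branch rather than a small-``theta`` plug-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "JointArea",
    "DEFAULT_AREAS",
    "AreaParams",
    "PatientHistory",
    "DataError",
    "nb_logpmf",
    "nb_pmf",
    "nb_log_weights",
    "truncated_nb_logpmf",
    "truncated_nb_pmf",
    "interval_intensity",
    "preclinic_logprob",
    "preclinic_prob",
    "validate_patient",
]

DAMAGE_COVARIATES = ("damage_hands", "damage_feet", "damage_large")


class DataError(ValueError):
    """Raised when a visit history violates the model's structural constraints."""


@dataclass(frozen=True)
class JointArea:
    """A joint area with a fixed capacity (total number of joints).

    The clinical areas are the 28 hand joints, 20 foot joints and 16 large
    joints; smaller capacities are accepted to support toy designs whose
    outcome space can be enumerated exhaustively.
    """

    label: str
    capacity: int

    def __post_init__(self) -> None:
        if self.capacity < 0:
            raise ValueError(f"capacity must be non-negative, got {self.capacity}")


DEFAULT_AREAS: tuple[JointArea, ...] = (
    JointArea("hands", 28),
    JointArea("feet", 20),
    JointArea("large", 16),
)


@dataclass
class AreaParams:
    """Progression parameters for one joint area.

    Parameters
    ----------
    lambda0
        Baseline intensity per year for in-clinic increments (> 0).
    beta
        Regression coefficients, ordered as the configured extra covariates
        followed by the three dynamic damage counts (hands, feet, large).
    theta
        NB dispersion for in-clinic increments (>= 0; 0 selects Poisson).
    lambda0_pre, theta_pre
        Baseline intensity and dispersion for the onset-to-entry period;
        ``None`` when no pre-clinic period is modelled.
    """

    lambda0: float
    beta: np.ndarray
    theta: float = 0.0
    lambda0_pre: float | None = None
    theta_pre: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be strictly positive")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.lambda0_pre is not None and self.lambda0_pre <= 0:
            raise ValueError("lambda0_pre must be strictly positive")
        if self.theta_pre is not None and self.theta_pre < 0:
            raise ValueError("theta_pre must be non-negative")


@dataclass
class PatientHistory:
    """One patient's intermittent observation record.

    ``visit_times`` are in years and strictly increasing; ``cum_damage`` maps
    each area label to the non-decreasing cumulative damaged-joint counts at
    the visits; ``active`` optionally gives current active-joint counts; any
    further per-visit covariates live in ``extra_covariates``.  A patient with
    a single visit has zero observed intervals.
    """

    patient_id: str
    onset_time: float
    visit_times: np.ndarray
    cum_damage: dict[str, np.ndarray]
    active: dict[str, np.ndarray] = field(default_factory=dict)
    extra_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    stayer_covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.visit_times = np.asarray(self.visit_times, dtype=float)
        self.cum_damage = {
            k: np.asarray(v, dtype=int) for k, v in self.cum_damage.items()
        }
        self.active = {k: np.asarray(v, dtype=int) for k, v in self.active.items()}
        self.extra_covariates = {
            k: np.asarray(v, dtype=float) for k, v in self.extra_covariates.items()
        }

    @property
    def n_visits(self) -> int:
        return len(self.visit_times)

    @property
    def onset_to_entry(self) -> float:
        return float(self.visit_times[0] - self.onset_time)


def validate_patient(
    patient: PatientHistory, areas: Sequence[JointArea] = DEFAULT_AREAS
) -> None:
    """Check the structural invariants of a visit history.

    Raises :class:`DataError` naming the patient and the violated constraint:
    at least one visit, strictly increasing visit times, onset before entry,
    and per area a non-decreasing cumulative count within capacity.
    """
    pid = patient.patient_id
    t = patient.visit_times
    if len(t) < 1:
        raise DataError(f"patient {pid}: at least one visit is required")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise DataError(
            f"patient {pid}: visit times must be strictly increasing "
            "(duplicate visit dates can be merged at load time)"
        )
    if patient.onset_time > t[0] + 1e-12:
        raise DataError(f"patient {pid}: onset time is after clinic entry")
    for area in areas:
        if area.label not in patient.cum_damage:
            raise DataError(f"patient {pid}: missing damage counts for {area.label!r}")
        n = patient.cum_damage[area.label]
        if len(n) != len(t):
            raise DataError(f"patient {pid}: {area.label} count length mismatch")
        if np.any(n < 0) or np.any(n > area.capacity):
            raise DataError(
                f"patient {pid}: {area.label} counts outside [0, {area.capacity}]"
            )
        if len(n) > 1 and np.any(np.diff(n) < 0):
            raise DataError(f"patient {pid}: {area.label} counts decrease over time")


# ---------------------------------------------------------------------------
# Negative binomial pmf, its Poisson limit, and right truncation
# ---------------------------------------------------------------------------


def nb_log_weights(theta: float, rmax: int) -> np.ndarray:
    """Log combinatorial weights ``c_r`` of the NB pmf for r = 0..rmax.

    The NB log pmf factorises as ``c_r + r*a - (1/theta) log(1+theta*mean)``
    with ``a = log(theta*mean / (1+theta*mean))`` and
    ``c_r = log Gamma(r+1/theta) - log Gamma(1/theta) - log r!``; at
    ``theta = 0`` the Poisson factorisation uses ``a = log(mean)`` and
    ``c_r = -log r!``.  Truncated pmfs over a capacity window only ever need
    ``c_r`` and ``a``, which is what the vectorised likelihood exploits.
    """
    r = np.arange(rmax + 1)
    if theta == 0.0:
        return -gammaln(r + 1.0)
    inv = 1.0 / theta
    return gammaln(r + inv) - gammaln(inv) - gammaln(r + 1.0)


def nb_logpmf(count, mean, dispersion: float):
    """Log pmf of the NB distribution with given mean and dispersion.

    ``dispersion = 0`` is the exact Poisson branch.  Accepts scalars or
    broadcastable arrays for ``count`` and ``mean``.
    """
    r = np.asarray(count)
    lam = np.asarray(mean, dtype=float)
    if np.any(r < 0):
        raise ValueError("count must be non-negative")
    if np.any(lam <= 0):
        raise ValueError("mean must be strictly positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if dispersion == 0.0:
        return r * np.log(lam) - lam - gammaln(r + 1.0)
    inv = 1.0 / dispersion
    tl = dispersion * lam
    return (
        gammaln(r + inv)
        - gammaln(inv)
        - gammaln(r + 1.0)
        + r * (np.log(tl) - np.log1p(tl))
        - inv * np.log1p(tl)
    )


def nb_pmf(count, mean, dispersion: float):
    """NB pmf ``f_nb(count | mean, dispersion)``; Poisson at dispersion 0."""
    return np.exp(nb_logpmf(count, mean, dispersion))


def truncated_nb_logpmf(count, mean, dispersion: float, upper: int):
    """Log pmf of the NB right-truncated to ``0..upper``.

    ``upper`` is the remaining undamaged capacity (``T^k - n`` for in-clinic
    increments, ``T^k`` for the onset-to-entry count).  ``upper = 0`` forces a
    point mass at zero.
    """
    if upper < 0:
        raise ValueError("upper must be non-negative")
    r = np.asarray(count)
    if np.any(r > upper):
        raise ValueError("count exceeds the truncation bound")
    if upper == 0:
        return np.zeros_like(np.asarray(r, dtype=float))
    log_num = nb_logpmf(count, mean, dispersion)
    log_den = logsumexp(nb_logpmf(np.arange(upper + 1), mean, dispersion))
    return log_num - log_den


def truncated_nb_pmf(count, mean, dispersion: float, upper: int):
    """Right-truncated NB pmf over the support ``0..upper``."""
    return np.exp(truncated_nb_logpmf(count, mean, dispersion, upper))


# ---------------------------------------------------------------------------
# Interval intensity with dynamic covariates
# ---------------------------------------------------------------------------


def interval_intensity(
    interval_length: float,
    dynamic_counts: Sequence[int],
    covariates: Mapping[str, float],
    area_params: AreaParams,
    extra_covariate_names: Sequence[str] = (),
) -> float:
    """NB mean for one inter-visit interval.

    ``Lambda = dt * lambda0 * exp(beta' z)`` where ``z`` stacks the extra
    covariates (in the configured order) followed by the three attained
    damage counts, all evaluated at the interval's left endpoint.
    """
    if interval_length <= 0:
        raise ValueError("interval_length must be strictly positive")
    beta = area_params.beta
    p = len(extra_covariate_names) + 3
    if len(beta) != p:
        raise ValueError(
            f"beta has length {len(beta)}, expected {p} "
            f"({len(extra_covariate_names)} extra covariates + 3 damage counts)"
        )
    z = []
    for name in extra_covariate_names:
        if name not in covariates:
            raise KeyError(f"configured covariate {name!r} missing")
        z.append(float(covariates[name]))
    z.extend(float(c) for c in dynamic_counts)
    lp = float(beta @ np.asarray(z))
    return interval_length * area_params.lambda0 * float(np.exp(lp))


def preclinic_logprob(
    count: int, onset_to_entry: float, area_params: AreaParams, area: JointArea
) -> float:
    """Log probability of ``count`` damaged joints between onset and entry.

    Truncated NB with mean ``onset_to_entry * lambda0_pre``, dispersion
    ``theta_pre`` and truncation at the full area capacity.  A zero
    onset-to-entry gap degenerates to a point mass at zero damage.
    """
    if count < 0 or count > area.capacity:
        raise ValueError(f"count must lie in [0, {area.capacity}]")
    if onset_to_entry < 0:
        raise ValueError("onset_to_entry must be non-negative")
    if onset_to_entry == 0.0:
        return 0.0 if count == 0 else -np.inf
    if area_params.lambda0_pre is None or area_params.theta_pre is None:
        raise ValueError("pre-clinic parameters are required when onset precedes entry")
    mean = onset_to_entry * area_params.lambda0_pre
    return float(
        truncated_nb_logpmf(count, mean, area_params.theta_pre, area.capacity)
    )


def preclinic_prob(
    count: int, onset_to_entry: float, area_params: AreaParams, area: JointArea
) -> float:
    """Probability of ``count`` damaged joints in the onset-to-entry period."""
    return float(np.exp(preclinic_logprob(count, onset_to_entry, area_params, area)))
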