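"""Shared fixtures and independent oracles for the test suite.

The quadrature helpers integrate the conditional likelihood against the
frailty density numerically (scipy.integrate), providing an oracle for the
closed-form signed expansions that never touches the expansion code path.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate, stats

from moverstayer import (
    AreaParams,
    JointArea,
    ModelParams,
    ModelSpec,
    PatientHistory,
    StayerParams,
)
from moverstayer.likelihood_onelevel import area_path_prob, conditional_patient_lik
from moverstayer.likelihood_twolevel import (
    TwoLevelModelParams,
    TwoLevelStayerParams,
    area_summary_twolevel,
    conditional_area_lik_twolevel,
)

TOY_AREAS = (JointArea("hands", 6), JointArea("feet", 5), JointArea("large", 4))


@pytest.fixture
def toy_areas():
    return TOY_AREAS


def frailty_dist(variance: float, family: str):
    """The unit-mean frailty distribution as a scipy frozen distribution."""
    if family == "gamma":
        return stats.gamma(a=1.0 / variance, scale=variance)
    return stats.invgauss(mu=variance, scale=1.0 / variance)


def random_patient(
    rng: np.random.Generator,
    areas=TOY_AREAS,
    with_preclinic: bool = False,
    n_visits: int | None = None,
) -> PatientHistory:
    """A random valid visit history on (by default) clipped-capacity areas."""
    m = n_visits or int(rng.integers(2, 5))
    times = np.cumsum(rng.uniform(0.3, 1.0, size=m))
    gap = float(rng.uniform(0.5, 4.0)) if with_preclinic else 0.0
    cum = {}
    for a in areas:
        start = int(rng.integers(0, a.capacity // 2 + 1)) if with_preclinic else 0
        incs = rng.integers(0, 2, size=m - 1)
        path = start + np.concatenate([[0], np.cumsum(incs)])
        cum[a.label] = np.minimum(path, a.capacity)
    return PatientHistory(
        patient_id=f"r{rng.integers(1e6)}",
        onset_time=float(times[0] - gap),
        visit_times=times,
        cum_damage=cum,
    )


def random_onelevel_config(rng: np.random.Generator, areas=TOY_AREAS):
    """Random (patient, params, spec) for a one-level variant."""
    with_pre = bool(rng.random() < 0.4)
    tmsp = bool(rng.random() < 0.25)
    family = "invgauss" if rng.random() < 0.3 else "gamma"
    patient = random_patient(rng, areas, with_preclinic=with_pre)
    area_params = {}
    for a in areas:
        theta = 0.0 if tmsp else float(rng.uniform(0.0, 8.0))
        area_params[a.label] = AreaParams(
            lambda0=float(rng.uniform(0.1, 1.0)),
            beta=rng.normal(0.0, 0.08, size=3),
            theta=theta,
            lambda0_pre=float(rng.uniform(0.1, 0.8)) if with_pre else None,
            theta_pre=(0.0 if tmsp else float(rng.uniform(0.0, 5.0)))
            if with_pre
            else None,
        )
    variance = float(rng.uniform(0.3, 5.0))
    stayer = StayerParams(
        alpha1={a.label: np.array([rng.uniform(-2.0, 1.0)]) for a in areas},
        gamma=variance if family == "gamma" else 1.0,
        frailty_family=family,
        psi=variance if family == "invgauss" else None,
    )
    spec = ModelSpec(
        variant="tmsp" if tmsp else "full", frailty_u=family, areas=areas
    )
    return patient, ModelParams(area_params, stayer), spec


def quadrature_marginal_onelevel(patient, params, spec) -> float:
    """1-D numerical integration of the patient likelihood over the frailty."""
    summaries = [
        area_path_prob(patient, a, params.areas[a.label], params, spec)
        for a in spec.areas
    ]
    dist = frailty_dist(params.stayer.variance, params.stayer.frailty_family)

    def integrand(u):
        return conditional_patient_lik(summaries, u) * dist.pdf(u)

    val, _ = integrate.quad(
        integrand, 0.0, np.inf, epsabs=1e-13, epsrel=1e-11, limit=500
    )
    return float(val)


def random_twolevel_config(rng: np.random.Generator, areas=TOY_AREAS):
    """Random (patient, params, spec) for the two-level model."""
    v_family = "gamma" if rng.random() < 0.4 else "invgauss"
    patient = random_patient(rng, areas, with_preclinic=bool(rng.random() < 0.7))
    area_params = {
        a.label: AreaParams(
            lambda0=float(rng.uniform(0.1, 1.0)),
            beta=rng.normal(0.0, 0.08, size=3),
            theta=float(rng.uniform(0.0, 8.0)),
            lambda0_pre=float(rng.uniform(0.1, 0.8)),
            theta_pre=float(rng.uniform(0.0, 5.0)),
        )
        for a in areas
    }
    stayer = TwoLevelStayerParams(
        alpha1={a.label: np.array([rng.uniform(-2.0, 1.0)]) for a in areas},
        alpha2={a.label: np.array([rng.uniform(-3.0, 0.5)]) for a in areas},
        gamma1=float(rng.uniform(0.3, 4.0)),
        v_family=v_family,
        variance2=float(rng.uniform(0.3, 3.0)),
    )
    spec = ModelSpec(variant="two_level", frailty_v=v_family, areas=areas)
    return patient, TwoLevelModelParams(area_params, stayer), spec


def quadrature_marginal_twolevel(patient, params, spec) -> float:
    """Tensor-product numerical integration over both frailties."""
    summaries = [
        area_summary_twolevel(patient, a, params.areas[a.label], params, spec)
        for a in spec.areas
    ]
    st = params.stayer
    du = frailty_dist(st.gamma1, "gamma")
    dv = frailty_dist(st.variance2, st.v_family)

    def inner(u):
        def f(v):
            lik = 1.0
            for s in summaries:
                lik *= conditional_area_lik_twolevel(s, u, v)
            return lik * dv.pdf(v)

        val, _ = integrate.quad(f, 0.0, np.inf, epsabs=1e-13, epsrel=1e-10, limit=300)
        return val * du.pdf(u)

    val, _ = integrate.quad(inner, 0.0, np.inf, epsabs=1e-12, epsrel=1e-9, limit=300)
    return float(val)


def enumerate_outcomes(areas, n_visits: int, with_preclinic: bool):
    """All visit histories on a toy design, for probability-coherence sums.

    Yields every combination of per-area monotone damage paths over
    ``n_visits`` visits (plus, optionally, a positive entry count from a
    pre-clinic period).
    """
    from itertools import product as iproduct

    times = 0.5 * np.arange(n_visits)
    onset = -2.0 if with_preclinic else 0.0

    def area_paths(cap):
        paths = []

        def extend(path):
            if len(path) == n_visits:
                paths.append(tuple(path))
                return
            for nxt in range(path[-1], cap + 1):
                extend(path + [nxt])

        for start in range(0, cap + 1) if with_preclinic else [0]:
            extend([start])
        return paths

    per_area = [area_paths(a.capacity) for a in areas]
    for combo in iproduct(*per_area):
        yield PatientHistory(
            patient_id="enum",
            onset_time=onset,
            visit_times=times,
            cum_damage={a.label: np.array(p) for a, p in zip(areas, combo)},
        )
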