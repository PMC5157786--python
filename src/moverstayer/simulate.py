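"""Synthetic data generation for the mover-stayer joint-damage model.

The generator reproduces the design of the parameter-recovery study: every
patient has a fixed number of equally spaced clinic visits, enters the
clinic damage free with arthritis onset at entry (no pre-clinic period), and
carries a gamma frailty ``U`` with unit mean and variance ``gamma``.  Per
area a Bernoulli mover indicator is drawn with success probability
``exp(-U * exp(alpha_k))``; stayers keep all-zero paths, movers accumulate
truncated negative binomial increments whose mean couples the areas through
the attained damage counts (dynamic covariates).

Randomness is organised through ``numpy.random.SeedSequence``: the dataset
seed spawns one child sequence per patient, and each patient's sequence
spawns one stream for the frailty and mover indicators plus one stream per
joint area for its increments, in area order.  Replicate ``r`` of a
simulation study uses the ``r``-th seed derived from the master seed, so
results are reproducible under by-replicate parallelism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .likelihood_onelevel import (
    ModelParams,
    ModelSpec,
    StayerParams,
    marginal_stayer_prob,
)
from .model_core import (
    DEFAULT_AREAS,
    AreaParams,
    JointArea,
    PatientHistory,
    nb_log_weights,
)

logger = logging.getLogger("moverstayer")

__all__ = [
    "SimDesign",
    "table4_design",
    "stayer_intercept",
    "simulate_patient",
    "simulate_dataset",
    "simulation_study",
    "StudyResult",
]


@dataclass
class SimDesign:
    """Generating truth and layout for a simulated cohort.

    ``area_params`` maps area labels to their generating parameters (no
    pre-clinic components are used), ``alpha1`` to the stayer intercepts.
    Defaults mirror the recovery-study conditions: 18 visits at 6-month
    spacing and a gamma frailty.
    """

    n_patients: int
    area_params: dict[str, AreaParams]
    alpha1: dict[str, float]
    gamma: float
    n_visits: int = 18
    inter_visit: float = 0.5
    include_preclinic: bool = False
    simulate_active: bool = False
    seed: int = 0
    areas: tuple[JointArea, ...] = DEFAULT_AREAS

    def __post_init__(self) -> None:
        if self.n_visits < 2:
            raise ValueError("n_visits must be at least 2")
        if self.inter_visit <= 0:
            raise ValueError("inter_visit must be strictly positive")
        if self.include_preclinic:
            raise ValueError(
                "pre-clinic simulation is not supported; onset coincides with entry"
            )

    def model_params(self) -> ModelParams:
        """The generating truth as a fittable parameter object."""
        return ModelParams(
            areas={k: v for k, v in self.area_params.items()},
            stayer=StayerParams(
                alpha1={k: np.array([v]) for k, v in self.alpha1.items()},
                gamma=self.gamma,
            ),
        )

    def spec(self) -> ModelSpec:
        return ModelSpec(variant="full", areas=self.areas)


def stayer_intercept(pi: float, variance: float, family: str = "gamma") -> float:
    """Invert the marginal stayer probability for an intercept-only model.

    For the gamma family solves ``pi = 1 - (1 + gamma e^a)^(-1/gamma)`` for
    ``a``; for the inverse Gaussian the corresponding closed form.
    """
    if not 0 < pi < 1:
        raise ValueError("pi must be in (0, 1)")
    if family == "gamma":
        return float(np.log(np.expm1(-variance * np.log1p(-pi)) / variance))
    if family == "invgauss":
        w = 1.0 - variance * np.log1p(-pi)
        return float(np.log((w**2 - 1.0) / (2.0 * variance)))
    raise ValueError(f"unknown frailty family {family!r}")


# The recovery-study truth: cross-process coefficients beta[target][source],
# baseline intensities, dispersions, frailty variance and marginal stayer
# probabilities per area.
TABLE4_TRUTH = {
    "beta": {
        "hands": {"hands": 0.1, "feet": 0.0, "large": 0.0},
        "feet": {"hands": 0.08, "feet": 0.04, "large": 0.1},
        "large": {"hands": 0.03, "feet": 0.0, "large": 0.0},
    },
    "lambda0": {"hands": 0.37, "feet": 0.61, "large": 0.14},
    "theta": {"hands": 8.0, "feet": 13.0, "large": 8.0},
    "gamma": 3.9,
    "pi1": {"hands": 0.37, "feet": 0.31, "large": 0.29},
}


def table4_design(n_patients: int, seed: int = 0) -> SimDesign:
    """The recovery-study design at its published true parameter values."""
    t = TABLE4_TRUTH
    labels = [a.label for a in DEFAULT_AREAS]
    area_params = {
        k: AreaParams(
            lambda0=t["lambda0"][k],
            beta=np.array([t["beta"][k][src] for src in labels]),
            theta=t["theta"][k],
        )
        for k in labels
    }
    alpha1 = {k: stayer_intercept(t["pi1"][k], t["gamma"]) for k in labels}
    return SimDesign(
        n_patients=n_patients,
        area_params=area_params,
        alpha1=alpha1,
        gamma=t["gamma"],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Patient and dataset simulation
# ---------------------------------------------------------------------------


def _trunc_cumsums(design: SimDesign):
    """Per-area cache of truncated-pmf cumulative sums keyed by the attained
    damage state, shared across patients of one dataset."""
    tables = []
    for area in design.areas:
        ap = design.area_params[area.label]
        tables.append(
            {
                "c_r": nb_log_weights(ap.theta, area.capacity),
                "r": np.arange(area.capacity + 1),
                "cache": {},
            }
        )
    return tables


def _increment_cumsum(design: SimDesign, a_idx: int, counts: tuple, tables) -> np.ndarray:
    area = design.areas[a_idx]
    ap = design.area_params[area.label]
    tab = tables[a_idx]
    key = counts
    cum = tab["cache"].get(key)
    if cum is None:
        upper = area.capacity - counts[a_idx]
        lam = design.inter_visit * ap.lambda0 * np.exp(
            float(ap.beta @ np.asarray(counts, dtype=float))
        )
        if ap.theta > 0:
            a_val = np.log(ap.theta * lam) - np.log1p(ap.theta * lam)
        else:
            a_val = np.log(lam)
        logits = tab["c_r"][: upper + 1] + tab["r"][: upper + 1] * a_val
        p = np.exp(logits - logsumexp(logits))
        cum = np.cumsum(p)
        cum /= cum[-1]
        tab["cache"][key] = cum
    return cum


def simulate_patient(
    design: SimDesign,
    rng: np.random.SeedSequence | np.random.Generator,
    patient_id: str = "p0",
    _tables=None,
    record: dict | None = None,
) -> PatientHistory:
    """Simulate one patient's visit history.

    ``rng`` is a ``SeedSequence`` (preferred: spawns the documented
    per-patient streams) or a ``Generator`` used for all draws.  Draw order:
    frailty ``u``, mover indicators per area, then per interval the area
    increments from categorical draws over the exact truncated NB pmf.
    """
    if isinstance(rng, np.random.SeedSequence):
        children = rng.spawn(1 + len(design.areas))
        g_pat = np.random.default_rng(children[0])
        g_area = [np.random.default_rng(c) for c in children[1:]]
    else:
        g_pat = rng
        g_area = [rng] * len(design.areas)
    tables = _tables if _tables is not None else _trunc_cumsums(design)
    K = len(design.areas)
    u = g_pat.gamma(shape=1.0 / design.gamma, scale=design.gamma)
    mover = np.array(
        [
            g_pat.random() < np.exp(-u * np.exp(design.alpha1[a.label]))
            for a in design.areas
        ]
    )
    if record is not None:
        record["u"] = float(u)
        record["mover"] = mover.copy()
    m = design.n_visits
    counts = np.zeros((m, K), dtype=int)
    state = np.zeros(K, dtype=int)
    for j in range(m - 1):
        key = tuple(state)
        for k in range(K):
            if not mover[k]:
                continue
            cum = _increment_cumsum(design, k, key, tables)
            d = int(np.searchsorted(cum, g_area[k].random(), side="right"))
            state[k] += d
        counts[j + 1] = state
    visit_times = design.inter_visit * np.arange(m)
    active = {}
    if design.simulate_active:
        for k, area in enumerate(design.areas):
            active[area.label] = np.minimum(
                g_area[k].poisson(2.0, size=m), area.capacity
            )
    return PatientHistory(
        patient_id=patient_id,
        onset_time=0.0,
        visit_times=visit_times,
        cum_damage={
            a.label: counts[:, k].copy() for k, a in enumerate(design.areas)
        },
        active=active,
    )


def simulate_dataset(design: SimDesign):
    """Simulate a cohort; returns ``(patients, truth)``.

    ``truth`` records the generating parameters (as :class:`ModelParams`)
    and the design, for recovery comparisons and sidecar serialisation.
    """
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(design.n_patients)
    tables = _trunc_cumsums(design)
    patients, records = [], []
    for i, child in enumerate(children):
        rec: dict = {}
        patients.append(
            simulate_patient(
                design, child, patient_id=f"p{i:05d}", _tables=tables, record=rec
            )
        )
        records.append(rec)
    truth = {
        "params": design.model_params(),
        "design": design,
        "frailties": np.array([r["u"] for r in records]),
        "movers": np.stack([r["mover"] for r in records]),
    }
    return patients, truth


# ---------------------------------------------------------------------------
# Simulation study harness
# ---------------------------------------------------------------------------


@dataclass
class StudyResult:
    """Replicate-level estimates and the summary recovery table.

    ``table`` has one row per reported parameter with the true value, the
    replicate-mean estimate, the mean estimated standard error, the standard
    deviation of the estimates, and the Monte-Carlo standard error of the
    mean.  ``estimates`` and ``ses`` hold the per-replicate values.
    """

    table: pd.DataFrame
    estimates: pd.DataFrame
    ses: pd.DataFrame
    n_failed: int
    failed_seeds: list[int] = field(default_factory=list)


def _recovery_names(design: SimDesign) -> dict[str, float]:
    truth: dict[str, float] = {}
    labels = [a.label for a in design.areas]
    for k in labels:
        ap = design.area_params[k]
        for s_idx, src in enumerate(labels):
            truth[f"beta_{src[0]}{k[0]}"] = float(ap.beta[s_idx])
        truth[f"lambda0_{k}"] = ap.lambda0
        truth[f"theta_{k}"] = ap.theta
        truth[f"pi1_{k}"] = float(
            marginal_stayer_prob(design.alpha1[k], design.gamma)
        )
    truth["gamma"] = design.gamma
    return truth


def simulation_study(
    design: SimDesign,
    n_reps: int,
    fit_spec: ModelSpec | None = None,
    master_seed: int | None = None,
    max_failed_frac: float = 0.2,
) -> StudyResult:
    """Simulate-and-refit recovery study in the published reporting format.

    Each replicate simulates a cohort from ``design`` (with a replicate seed
    derived from ``master_seed``), fits ``fit_spec`` (default: the full
    model), and records natural-scale estimates and standard errors for the
    regression coefficients, baseline intensities, dispersions, marginal
    stayer probabilities and the frailty variance.  Failed fits are excluded
    and counted; more than ``max_failed_frac`` failures raises.
    """
    from .inference import fit_model  # local import to avoid a cycle

    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    fit_spec = fit_spec or design.spec()
    master_seed = design.seed if master_seed is None else master_seed
    rep_seeds = (
        np.random.SeedSequence(master_seed).generate_state(n_reps) & 0x7FFFFFFF
    )
    truth = _recovery_names(design)
    est_rows, se_rows, failed = [], [], []
    for r in range(n_reps):
        d_r = replace(design, seed=int(rep_seeds[r]))
        patients, _ = simulate_dataset(d_r)
        fit = fit_model(patients, fit_spec)
        if not fit.converged or fit.boundary:
            failed.append(int(rep_seeds[r]))
            logger.warning("replicate %d failed (convergence/boundary); excluded", r)
            continue
        est, se = {}, {}
        labels = [a.label for a in design.areas]
        for k in labels:
            ap = fit.params.areas[k]
            for s_idx, src in enumerate(labels):
                name = f"beta_{src[0]}{k[0]}"
                est[name] = float(ap.beta[s_idx])
                se[name] = fit.se_natural.get(f"{k}.beta.damage_{src}", np.nan)
            est[f"lambda0_{k}"] = ap.lambda0
            se[f"lambda0_{k}"] = fit.se_natural.get(f"{k}.lambda0", np.nan)
            est[f"theta_{k}"] = ap.theta
            se[f"theta_{k}"] = fit.se_natural.get(f"{k}.theta", np.nan)
            est[f"pi1_{k}"], se[f"pi1_{k}"] = fit.derived[f"p_stayer_{k}"][:2]
        est["gamma"] = fit.params.stayer.variance
        se["gamma"] = fit.se_natural.get("gamma", np.nan)
        est_rows.append(est)
        se_rows.append(se)
    n_failed = len(failed)
    if n_failed > max_failed_frac * n_reps:
        raise RuntimeError(
            f"{n_failed}/{n_reps} replicates failed to converge; study aborted"
        )
    est_df = pd.DataFrame(est_rows)
    se_df = pd.DataFrame(se_rows)
    rows = []
    for name, tval in truth.items():
        e = est_df[name]
        rows.append(
            {
                "parameter": name,
                "true": tval,
                "mean": e.mean(),
                "mean_se": se_df[name].mean(),
                "sd": e.std(ddof=1),
                "mc_se": e.std(ddof=1) / np.sqrt(len(e)),
            }
        )
    return StudyResult(
        table=pd.DataFrame(rows),
        estimates=est_df,
        ses=se_df,
        n_failed=n_failed,
        failed_seeds=failed,
    )
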