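"""Maximum-likelihood fitting, standard errors and profile likelihoods.

All positivity-constrained parameters (baseline intensities, dispersions,
frailty variances) are optimised on the log scale; regression coefficients
and stayer intercepts on the identity scale.  Optimisation uses BFGS; the
one-level variants supply the analytic score of the packed likelihood,
while the two-level model uses finite-difference gradients and, because its
clinic-induced component can be weakly identified, a small multi-start.

Uncertainty comes from the observed information (negative Hessian of the
log-likelihood at the optimum, by central finite differences), inverted via
a pseudo-inverse; Wald intervals are mapped back to the natural scale, and
derived marginal stayer probabilities get delta-method standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .likelihood_onelevel import (
    ModelParams,
    ModelSpec,
    PackedData,
    StayerParams,
    marginal_stayer_prob,
)
from .model_core import AreaParams, PatientHistory

logger = logging.getLogger("moverstayer")

__all__ = [
    "Parameterization",
    "FitResult",
    "fit_model",
    "observed_information",
    "delta_method_se",
    "profile_loglik",
    "default_init",
]

DAMAGE_NAMES = ("damage_hands", "damage_feet", "damage_large")
_BOUNDARY = 30.0


class Parameterization:
    """Bijection between structured parameters and a flat working vector.

    Working-scale block order: per area ``log lambda0``, ``beta`` (extras
    then damage counts), ``log theta`` (unless truncated Poisson),
    ``log lambda0_pre``/``log theta_pre`` when a pre-clinic period is
    present; then per area the stayer coefficients ``alpha1`` (and
    ``alpha2`` for the two-level model); finally the log frailty
    variance(s).
    """

    def __init__(self, spec: ModelSpec, has_preclinic: bool = False):
        self.spec = spec
        self.has_preclinic = has_preclinic
        self.two_level = spec.variant == "two_level"
        labels = spec.area_labels
        damage = tuple(f"damage_{k}" for k in labels)
        self.beta_names = tuple(spec.extra_covariates) + damage
        self.alpha_names = ("intercept",) + tuple(spec.stayer_covariates)
        names: list[str] = []
        transforms: list[str] = []

        def add(name: str, tr: str) -> None:
            names.append(name)
            transforms.append(tr)

        for k in labels:
            add(f"{k}.log_lambda0", "exp")
            for b in self.beta_names:
                add(f"{k}.beta.{b}", "id")
            if spec.has_dispersion:
                add(f"{k}.log_theta", "exp")
            if has_preclinic:
                add(f"{k}.log_lambda0_pre", "exp")
                if spec.has_dispersion:
                    add(f"{k}.log_theta_pre", "exp")
        if spec.variant != "tnb":
            for k in labels:
                for a in self.alpha_names:
                    add(f"{k}.alpha1.{a}", "id")
            if self.two_level:
                for k in labels:
                    for a in self.alpha_names:
                        add(f"{k}.alpha2.{a}", "id")
            u_name = "log_gamma" if spec.frailty_u == "gamma" else "log_psi"
            if self.two_level:
                add("log_gamma1", "exp")
                add(
                    "log_gamma2" if spec.frailty_v == "gamma" else "log_psi2", "exp"
                )
            else:
                add(u_name, "exp")
        self.names = names
        self.transforms = transforms
        self.n = len(names)
        self._index = {n: i for i, n in enumerate(names)}

    def index(self, name: str) -> int:
        return self._index[name]

    def pack(self, params) -> np.ndarray:
        spec = self.spec
        x = np.empty(self.n)
        i = 0
        for k in spec.area_labels:
            ap = params.areas[k]
            x[i] = np.log(ap.lambda0)
            i += 1
            nb = len(self.beta_names)
            x[i : i + nb] = ap.beta
            i += nb
            if spec.has_dispersion:
                x[i] = np.log(max(ap.theta, 1e-12))
                i += 1
            if self.has_preclinic:
                x[i] = np.log(ap.lambda0_pre)
                i += 1
                if spec.has_dispersion:
                    x[i] = np.log(max(ap.theta_pre, 1e-12))
                    i += 1
        if spec.variant != "tnb":
            st = params.stayer
            na = len(self.alpha_names)
            for k in spec.area_labels:
                x[i : i + na] = st.alpha1[k]
                i += na
            if self.two_level:
                for k in spec.area_labels:
                    x[i : i + na] = st.alpha2[k]
                    i += na
                x[i] = np.log(st.gamma1)
                x[i + 1] = np.log(st.variance2)
                i += 2
            else:
                x[i] = np.log(st.variance)
                i += 1
        assert i == self.n
        return x

    def unpack(self, x: np.ndarray):
        spec = self.spec
        areas: dict[str, AreaParams] = {}
        i = 0
        nb = len(self.beta_names)
        for k in spec.area_labels:
            lam0 = float(np.exp(x[i]))
            i += 1
            beta = np.array(x[i : i + nb])
            i += nb
            theta = 0.0
            if spec.has_dispersion:
                theta = float(np.exp(x[i]))
                i += 1
            lam0_pre = theta_pre = None
            if self.has_preclinic:
                lam0_pre = float(np.exp(x[i]))
                i += 1
                theta_pre = 0.0
                if spec.has_dispersion:
                    theta_pre = float(np.exp(x[i]))
                    i += 1
            areas[k] = AreaParams(lam0, beta, theta, lam0_pre, theta_pre)
        stayer = None
        if spec.variant != "tnb":
            na = len(self.alpha_names)
            alpha1 = {}
            for k in spec.area_labels:
                alpha1[k] = np.array(x[i : i + na])
                i += na
            if self.two_level:
                from .likelihood_twolevel import (
                    TwoLevelModelParams,
                    TwoLevelStayerParams,
                )

                alpha2 = {}
                for k in spec.area_labels:
                    alpha2[k] = np.array(x[i : i + na])
                    i += na
                stayer = TwoLevelStayerParams(
                    alpha1=alpha1,
                    alpha2=alpha2,
                    gamma1=float(np.exp(x[i])),
                    v_family=spec.frailty_v,
                    variance2=float(np.exp(x[i + 1])),
                )
                i += 2
                return TwoLevelModelParams(areas=areas, stayer=stayer)
            var = float(np.exp(x[i]))
            i += 1
            stayer = StayerParams(
                alpha1=alpha1,
                gamma=var if spec.frailty_u == "gamma" else 1.0,
                frailty_family=spec.frailty_u,
                psi=var if spec.frailty_u == "invgauss" else None,
            )
        return ModelParams(areas=areas, stayer=stayer)

    def natural_name(self, name: str) -> str:
        return name.replace("log_", "")

    def natural(self, x: np.ndarray) -> dict[str, float]:
        out = {}
        for i, (n, tr) in enumerate(zip(self.names, self.transforms)):
            v = float(x[i])
            out[self.natural_name(n)] = float(np.exp(v)) if tr == "exp" else v
        return out


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics from a maximum-likelihood fit."""

    spec: ModelSpec
    params: object  # ModelParams or TwoLevelModelParams on the natural scale
    names: list[str]
    x: np.ndarray  # working-scale estimates
    max_loglik: float
    covariance: np.ndarray  # working scale
    se_working: dict[str, float]
    se_natural: dict[str, float]
    wald_intervals: dict[str, tuple[float, float]]  # natural scale, 95%
    derived: dict[str, tuple[float, float, float, float]]  # (est, se, lo, hi)
    converged: bool
    n_iter: int
    grad_norm: float
    boundary: bool
    message: str
    estimates_natural: dict[str, float] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for n in self.names:
            nat = n.replace("log_", "")
            lo, hi = self.wald_intervals[nat]
            rows.append(
                {
                    "parameter": nat,
                    "estimate": self.estimates_natural[nat],
                    "se": self.se_natural[nat],
                    "ci_lower": lo,
                    "ci_upper": hi,
                }
            )
        for n, (est, se, lo, hi) in self.derived.items():
            rows.append(
                {"parameter": n, "estimate": est, "se": se, "ci_lower": lo, "ci_upper": hi}
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Numerical differentiation
# ---------------------------------------------------------------------------


def observed_information(
    loglik_fn: Callable[[np.ndarray], float],
    at: np.ndarray,
    rel_step: float = 1e-4,
    grad_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Negative Hessian of ``loglik_fn`` at ``at`` by central differences.

    When ``grad_fn`` is supplied the Hessian is the central-difference
    Jacobian of the gradient (one order cheaper and more accurate);
    otherwise second differences of the log-likelihood are used.  The result
    is symmetrised.  Non-finite entries raise, naming the coordinate.
    """
    at = np.asarray(at, dtype=float)
    p = len(at)
    h = rel_step * np.maximum(1.0, np.abs(at))
    H = np.empty((p, p))
    if grad_fn is not None:
        for i in range(p):
            e = np.zeros(p)
            e[i] = h[i]
            H[:, i] = (grad_fn(at + e) - grad_fn(at - e)) / (2 * h[i])
    else:
        f0 = loglik_fn(at)
        fp = np.empty(p)
        fm = np.empty(p)
        for i in range(p):
            e = np.zeros(p)
            e[i] = h[i]
            fp[i] = loglik_fn(at + e)
            fm[i] = loglik_fn(at - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(p):
            for j in range(i + 1, p):
                ei = np.zeros(p)
                ej = np.zeros(p)
                ei[i] = h[i]
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    loglik_fn(at + ei + ej)
                    - loglik_fn(at + ei - ej)
                    - loglik_fn(at - ei + ej)
                    + loglik_fn(at - ei - ej)
                ) / (4 * h[i] * h[j])
    H = 0.5 * (H + H.T)
    bad = np.argwhere(~np.isfinite(H))
    if len(bad):
        i, j = bad[0]
        raise FloatingPointError(
            f"non-finite observed-information entry at coordinates ({i}, {j})"
        )
    return -H


def covariance_from_information(info: np.ndarray, cond_warn: float = 1e10) -> np.ndarray:
    """Pseudo-inverse of the observed information, with a conditioning warning."""
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > cond_warn:
        logger.warning("observed information is ill-conditioned (cond=%.3g)", cond)
    cov = np.linalg.pinv(info)
    return 0.5 * (cov + cov.T)


def delta_method_se(
    transform: Callable[[np.ndarray], float],
    at: np.ndarray,
    covariance: np.ndarray,
    rel_step: float = 1e-6,
) -> float:
    """Standard error of ``transform(params)`` by first-order propagation."""
    at = np.asarray(at, dtype=float)
    p = len(at)
    g = np.empty(p)
    h = rel_step * np.maximum(1.0, np.abs(at))
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        g[i] = (transform(at + e) - transform(at - e)) / (2 * h[i])
    return float(np.sqrt(max(g @ covariance @ g, 0.0)))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def default_init(
    data: Sequence[PatientHistory], spec: ModelSpec, par: Parameterization
) -> np.ndarray:
    """Data-driven starting values on the working scale.

    Baseline intensities start at crude events per person-year, stayer
    intercepts at the complementary-log-log inverse of the damage-free
    fraction, dispersions and frailty variances at one, and all regression
    slopes at zero.
    """
    x = np.zeros(par.n)
    for k_idx, area in enumerate(spec.areas):
        k = area.label
        tot_d = tot_t = 0.0
        tot_pre_d = tot_pre_t = 0.0
        n_free = 0
        for pt in data:
            n = pt.cum_damage[k]
            tot_d += float(n[-1] - n[0])
            tot_t += float(pt.visit_times[-1] - pt.visit_times[0])
            tot_pre_d += float(n[0])
            tot_pre_t += pt.onset_to_entry
            n_free += int(n[-1] == 0)
        lam0 = max(tot_d / max(tot_t, 1e-9), 1e-3)
        x[par.index(f"{k}.log_lambda0")] = np.log(lam0)
        if par.has_preclinic:
            lam0p = max(tot_pre_d / max(tot_pre_t, 1e-9), 1e-3)
            x[par.index(f"{k}.log_lambda0_pre")] = np.log(lam0p)
        if spec.variant != "tnb":
            frac = np.clip(n_free / len(data), 0.02, 0.98)
            x[par.index(f"{k}.alpha1.intercept")] = np.log(-np.log1p(-frac))
            if par.two_level:
                x[par.index(f"{k}.alpha2.intercept")] = -3.0
    return x


def _make_objective(packed: PackedData, par: Parameterization):
    def nll(x: np.ndarray):
        if np.any(np.abs(x) > 2 * _BOUNDARY):
            return 1e10 + float(x @ x), 2.0 * x
        params = par.unpack(x)
        ll, g = packed.loglik_and_grad(params, want_grad=True)
        if not np.isfinite(ll) or g is None or not np.all(np.isfinite(g)):
            return 1e10 + float(x @ x), 2.0 * x
        return -ll, -g

    return nll


def _make_objective_numeric(loglik_of_x: Callable[[np.ndarray], float]):
    def nll(x: np.ndarray):
        if np.any(np.abs(x) > 2 * _BOUNDARY):
            return 1e10 + float(x @ x)
        ll = loglik_of_x(x)
        if not np.isfinite(ll):
            return 1e10 + float(x @ x)
        return -ll

    return nll


def fit_model(
    data: Sequence[PatientHistory],
    spec: ModelSpec,
    init: object | None = None,
    seed: int | None = None,
    gtol: float = 1e-5,
    maxiter: int = 1000,
    n_starts: int | None = None,
    compute_uncertainty: bool = True,
) -> FitResult:
    """Fit a model variant by maximum likelihood.

    ``init`` may be a working-scale vector, a parameter object, or ``None``
    for the data-driven default.  The two-level model defaults to five
    jittered starts (deterministic given ``seed``) because its
    clinic-induced component can sit near the boundary of identifiability.
    Non-convergence is reported through ``FitResult.converged`` rather than
    an exception; working parameters drifting beyond +-30 set ``boundary``.
    """
    if spec.variant == "two_level":
        from .likelihood_twolevel import packed_twolevel_loglik

        has_pre = any(p.onset_to_entry > 0 for p in data)
        par = Parameterization(spec, has_preclinic=has_pre)
        loglik_of_x = packed_twolevel_loglik(data, spec, par)
        nll = _make_objective_numeric(loglik_of_x)
        jac = None
        loglik_fn = loglik_of_x
        grad_fn = None
        if n_starts is None:
            n_starts = 5
    else:
        packed = PackedData(data, spec)
        par = Parameterization(spec, has_preclinic=packed.has_preclinic)
        nll = _make_objective(packed, par)
        jac = True
        loglik_fn = lambda x: packed.loglik(par.unpack(x))  # noqa: E731
        grad_fn = lambda x: packed.loglik_and_grad(par.unpack(x))[1]  # noqa: E731
        if n_starts is None:
            n_starts = 1

    if init is None:
        x0 = default_init(data, spec, par)
    elif isinstance(init, np.ndarray):
        x0 = np.asarray(init, dtype=float)
    else:
        x0 = par.pack(init)

    rng = np.random.default_rng(0 if seed is None else seed)
    starts = [x0] + [
        x0 + rng.normal(scale=0.3, size=par.n) for _ in range(n_starts - 1)
    ]
    best = None
    for s in starts:
        res = minimize(
            nll,
            s,
            jac=jac,
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    res = best
    x_hat = res.x
    max_ll = -float(res.fun)
    boundary = bool(np.any(np.abs(x_hat) > _BOUNDARY))
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    converged = bool(res.success or grad_norm < 1e-3)
    if boundary:
        logger.warning("working parameter beyond +-%.0f: boundary flag set", _BOUNDARY)

    params_hat = par.unpack(x_hat)
    se_w: dict[str, float] = {}
    se_n: dict[str, float] = {}
    wald: dict[str, tuple[float, float]] = {}
    derived: dict[str, tuple[float, float, float, float]] = {}
    cov = np.full((par.n, par.n), np.nan)
    if compute_uncertainty and converged and not boundary:
        try:
            info = observed_information(loglik_fn, x_hat, grad_fn=grad_fn)
            cov = covariance_from_information(info)
        except FloatingPointError as exc:
            logger.warning("observed information failed: %s", exc)
    z = 1.959963984540054
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    natural = par.natural(x_hat)
    for i, (name, tr) in enumerate(zip(par.names, par.transforms)):
        nat = par.natural_name(name)
        se_w[name] = float(sd[i])
        lo, hi = x_hat[i] - z * sd[i], x_hat[i] + z * sd[i]
        if tr == "exp":
            se_n[nat] = float(np.exp(x_hat[i]) * sd[i])
            wald[nat] = (float(np.exp(lo)), float(np.exp(hi)))
        else:
            se_n[nat] = float(sd[i])
            wald[nat] = (float(lo), float(hi))

    if spec.variant in ("full", "tmsp", "two_level"):
        derived.update(_derived_stayer_probs(spec, par, x_hat, cov))

    return FitResult(
        spec=spec,
        params=params_hat,
        names=par.names,
        x=x_hat,
        max_loglik=max_ll,
        covariance=cov,
        se_working=se_w,
        se_natural=se_n,
        wald_intervals=wald,
        derived=derived,
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        boundary=boundary,
        message=str(res.message),
        estimates_natural=natural,
    )


def _derived_stayer_probs(spec, par, x_hat, cov):
    """Marginal stayer probabilities at the intercept, with delta-method SEs.

    With stayer covariates present the probabilities are evaluated at zero
    covariate values (the intercept patient).
    """
    z = 1.959963984540054
    out = {}
    levels = [("p_stayer", "alpha1")]
    if par.two_level:
        levels = [("p_true_stayer", "alpha1"), ("p_clinic_stayer", "alpha2")]
    for prefix, block in levels:
        if par.two_level:
            var_name = "log_gamma1" if block == "alpha1" else (
                "log_gamma2" if spec.frailty_v == "gamma" else "log_psi2"
            )
            family = "gamma" if block == "alpha1" else spec.frailty_v
        else:
            var_name = "log_gamma" if spec.frailty_u == "gamma" else "log_psi"
            family = spec.frailty_u
        iv = par.index(var_name)
        for k in spec.area_labels:
            ia = par.index(f"{k}.{block}.intercept")

            def transform(x, ia=ia, iv=iv, family=family):
                return float(marginal_stayer_prob(x[ia], np.exp(x[iv]), family))

            est = transform(x_hat)
            se = (
                delta_method_se(transform, x_hat, cov)
                if np.all(np.isfinite(cov))
                else np.nan
            )
            out[f"{prefix}_{k}"] = (est, se, est - z * se, est + z * se)
    return out


def profile_loglik(
    data: Sequence[PatientHistory],
    spec: ModelSpec,
    target: str,
    grid: Sequence[float],
    init: object | None = None,
    gtol: float = 1e-5,
    maxiter: int = 500,
) -> pd.DataFrame:
    """Profile log-likelihood over a working-scale grid for one parameter.

    For each grid value the target coordinate is fixed and all remaining
    parameters are re-maximised, warm-started from the previous grid point.
    Returns a frame with columns ``value``, ``loglik`` and ``converged``.
    """
    if spec.variant == "two_level":
        from .likelihood_twolevel import packed_twolevel_loglik

        has_pre = any(p.onset_to_entry > 0 for p in data)
        par = Parameterization(spec, has_preclinic=has_pre)
        loglik_of_x = packed_twolevel_loglik(data, spec, par)
        full_nll = _make_objective_numeric(loglik_of_x)
        use_jac = False
    else:
        packed = PackedData(data, spec)
        par = Parameterization(spec, has_preclinic=packed.has_preclinic)
        full = _make_objective(packed, par)
        full_nll = full
        use_jac = True
    idx = par.index(target)
    free = np.array([i for i in range(par.n) if i != idx])

    if init is None:
        x_cur = default_init(data, spec, par)
    elif isinstance(init, FitResult):
        x_cur = init.x.copy()
    elif isinstance(init, np.ndarray):
        x_cur = np.asarray(init, dtype=float).copy()
    else:
        x_cur = par.pack(init)

    rows = []
    for v in grid:
        x_cur[idx] = v

        if use_jac:

            def nll_red(xf):
                x = x_cur.copy()
                x[free] = xf
                f, g = full_nll(x)
                return f, g[free]

        else:

            def nll_red(xf):
                x = x_cur.copy()
                x[free] = xf
                return full_nll(x)

        res = minimize(
            nll_red,
            x_cur[free],
            jac=use_jac if use_jac else None,
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        x_cur[free] = res.x
        ok = bool(res.success or (np.max(np.abs(np.atleast_1d(res.jac))) < 1e-3))
        if not ok:
            logger.warning("profile point %s=%.4g did not fully converge", target, v)
        rows.append({"value": float(v), "loglik": -float(res.fun), "converged": ok})
    return pd.DataFrame(rows)
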