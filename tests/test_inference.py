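"""Fitting machinery: information matrix, delta method, profiles, recovery."""

import numpy as np
import pytest

from moverstayer import (
    ModelParams,
    ModelSpec,
    delta_method_se,
    fit_model,
    observed_information,
    profile_loglik,
    simulate_dataset,
    table4_design,
)
from moverstayer.inference import Parameterization, covariance_from_information
from moverstayer.simulate import SimDesign, stayer_intercept

from conftest import TOY_AREAS, random_onelevel_config


@pytest.fixture(scope="module")
def small_fit():
    """A full-model fit on a modest simulated cohort, shared across tests."""
    design = table4_design(150, seed=314)
    patients, truth = simulate_dataset(design)
    fit = fit_model(patients, design.spec())
    return design, patients, truth, fit


class TestObservedInformation:
    def test_exact_for_quadratic(self):
        A = np.array([[2.0, 0.3], [0.3, 1.0]])

        def ll(x):
            return -0.5 * x @ A @ x

        info = observed_information(ll, np.array([0.4, -0.2]))
        np.testing.assert_allclose(info, A, atol=1e-6)

    def test_poisson_closed_form(self):
        x = np.array([3.0, 1.0, 4.0, 2.0])

        def ll(lam):
            return float(np.sum(x * np.log(lam[0]) - lam[0]))

        lam_hat = x.mean()
        info = observed_information(ll, np.array([lam_hat]))
        assert info[0, 0] == pytest.approx(len(x) * x.mean() / lam_hat**2, rel=1e-5)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(3, 3))
        A = A @ A.T + np.eye(3)

        def ll(x):
            return -0.5 * x @ A @ x + 0.1 * x[0] * x[1] * x[2]

        info = observed_information(ll, np.array([0.1, 0.2, -0.1]))
        np.testing.assert_array_equal(info, info.T)


class TestDeltaMethod:
    COV = np.array([[0.04, 0.01], [0.01, 0.09]])

    def test_identity_returns_sqrt_diagonal(self):
        at = np.array([1.0, 2.0])
        assert delta_method_se(lambda x: x[0], at, self.COV) == pytest.approx(0.2)
        assert delta_method_se(lambda x: x[1], at, self.COV) == pytest.approx(0.3)

    def test_linear_transform_exact(self):
        a = np.array([2.0, -1.0])
        se = delta_method_se(lambda x: a @ x, np.array([0.5, 0.5]), self.COV)
        assert se == pytest.approx(np.sqrt(a @ self.COV @ a), rel=1e-8)


class TestParameterization:
    @pytest.mark.parametrize("variant", ["full", "tnb", "tmsp", "two_level"])
    def test_pack_unpack_roundtrip(self, variant):
        rng = np.random.default_rng(11)
        spec = ModelSpec(variant=variant, areas=TOY_AREAS)
        par = Parameterization(spec, has_preclinic=(variant != "tnb"))
        x = rng.normal(scale=0.5, size=par.n)
        x2 = par.pack(par.unpack(x))
        np.testing.assert_allclose(x2, x, atol=1e-12)
        assert len(par.names) == par.n


class TestFitModel:
    def test_recovers_truth_within_sampling_error(self, small_fit):
        design, _, _, fit = small_fit
        assert fit.converged and not fit.boundary
        # 3 sigma bands from the reported SEs around the generating values
        checks = [
            ("hands", 0, 0.1),  # hand damage on hand progression
            ("feet", 0, 0.08),
            ("feet", 2, 0.1),
        ]
        for area, j, true in checks:
            est = fit.params.areas[area].beta[j]
            se = fit.se_natural[
                f"{area}.beta.damage_{['hands', 'feet', 'large'][j]}"
            ]
            assert abs(est - true) < 4 * se

    def test_refit_from_optimum_is_fixed_point(self, small_fit):
        design, patients, _, fit = small_fit
        refit = fit_model(patients, design.spec(), init=fit.x, compute_uncertainty=False)
        assert abs(refit.max_loglik - fit.max_loglik) < 1e-6

    def test_wald_intervals_bracket_estimates(self, small_fit):
        _, _, _, fit = small_fit
        for name in fit.names:
            nat = name.replace("log_", "")
            lo, hi = fit.wald_intervals[nat]
            est = fit.estimates_natural[nat]
            assert lo < est < hi

    def test_natural_estimates_respect_positivity(self, small_fit):
        _, _, _, fit = small_fit
        for k in ("hands", "feet", "large"):
            assert fit.params.areas[k].lambda0 > 0
            assert fit.params.areas[k].theta >= 0
        assert fit.params.stayer.gamma > 0

    def test_stayer_free_data_behaves_like_tnb(self):
        # data generated with a negligible stayer fraction: the full model's
        # stayer component collapses and its fit approaches the TNB fit
        design = table4_design(150, seed=77)
        design = SimDesign(
            n_patients=150,
            area_params=design.area_params,
            alpha1={
                k: stayer_intercept(1e-3, design.gamma) for k in design.alpha1
            },
            gamma=design.gamma,
            n_visits=10,
            seed=77,
        )
        patients, _ = simulate_dataset(design)
        full = fit_model(patients, ModelSpec(variant="full"), compute_uncertainty=False)
        tnb = fit_model(patients, ModelSpec(variant="tnb"), compute_uncertainty=False)
        for k in ("hands", "feet", "large"):
            assert full.derived[f"p_stayer_{k}"][0] < 0.1
        assert full.max_loglik >= tnb.max_loglik - 1e-3
        assert full.max_loglik - tnb.max_loglik < 3.0

    def test_delta_se_agrees_with_parametric_bootstrap(self, small_fit):
        design, patients, _, fit = small_fit
        est, se = fit.derived["p_stayer_hands"][:2]
        rng = np.random.default_rng(5)
        boots = []
        from dataclasses import replace

        fitted_design = replace(
            design,
            area_params={k: fit.params.areas[k] for k in design.area_params},
            alpha1={
                k: float(fit.params.stayer.alpha1[k][0]) for k in design.alpha1
            },
            gamma=fit.params.stayer.gamma,
        )
        for b in range(40):
            d_b = replace(fitted_design, seed=int(rng.integers(2**31)))
            pats_b, _ = simulate_dataset(d_b)
            fit_b = fit_model(pats_b, design.spec(), compute_uncertainty=False)
            if fit_b.converged:
                boots.append(fit_b.derived["p_stayer_hands"][0])
        boot_se = np.std(boots, ddof=1)
        assert se == pytest.approx(boot_se, rel=0.35)


class TestTwoLevelFit:
    def test_two_level_fit_runs_and_improves_on_init(self):
        """The two-level model fits end-to-end on a small cohort with
        pre-clinic damage, improving on the starting values."""
        from conftest import TOY_AREAS, random_patient
        from moverstayer.inference import default_init
        from moverstayer.likelihood_twolevel import packed_twolevel_loglik

        rng = np.random.default_rng(21)
        pats = [
            random_patient(rng, TOY_AREAS, with_preclinic=True, n_visits=3)
            for _ in range(25)
        ]
        spec = ModelSpec(variant="two_level", areas=TOY_AREAS)
        fit = fit_model(
            pats, spec, n_starts=1, maxiter=80, compute_uncertainty=False
        )
        par = Parameterization(spec, has_preclinic=True)
        ll0 = packed_twolevel_loglik(pats, spec, par)(default_init(pats, spec, par))
        assert np.isfinite(fit.max_loglik)
        assert fit.max_loglik > ll0
        st = fit.params.stayer
        assert st.gamma1 > 0 and st.variance2 > 0
        assert set(fit.derived) == {
            f"{p}_{k}"
            for p in ("p_true_stayer", "p_clinic_stayer")
            for k in ("hands", "feet", "large")
        }


class TestProfileLoglik:
    def test_profile_touches_maximum_at_mle(self, small_fit):
        design, patients, _, fit = small_fit
        idx = fit.names.index("log_gamma")
        mle_val = fit.x[idx]
        grid = [mle_val - 0.4, mle_val, mle_val + 0.4]
        curve = profile_loglik(patients, design.spec(), "log_gamma", grid, init=fit)
        assert curve["loglik"].iloc[1] == pytest.approx(fit.max_loglik, abs=1e-5)
        assert curve["loglik"].iloc[1] >= curve["loglik"].iloc[0]
        assert curve["loglik"].iloc[1] >= curve["loglik"].iloc[2]

    def test_monotone_decline_away_from_mle(self, small_fit):
        design, patients, _, fit = small_fit
        idx = fit.names.index("hands.alpha1.intercept")
        v0 = fit.x[idx]
        grid = [v0, v0 + 0.5, v0 + 1.0, v0 + 1.5]
        curve = profile_loglik(
            patients, design.spec(), "hands.alpha1.intercept", grid, init=fit
        )
        ll = curve["loglik"].to_numpy()
        assert np.all(np.diff(ll) < 0)


class TestCovariance:
    def test_ill_conditioned_information_warns(self, caplog):
        info = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-14]])
        import logging

        with caplog.at_level(logging.WARNING, logger="moverstayer"):
            covariance_from_information(info)
        assert any("ill-conditioned" in r.message for r in caplog.records)
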