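"""One-level marginal likelihood: expansion, links, nesting, packed engine."""

import numpy as np
import pytest
from scipy import integrate, stats

from moverstayer import (
    AreaParams,
    ModelParams,
    ModelSpec,
    PackedData,
    PatientHistory,
    StayerParams,
    dataset_loglik,
    marginal_patient_lik,
    marginal_patient_loglik,
    marginal_stayer_prob_gamma,
    marginal_stayer_prob_invgauss,
)
from moverstayer.inference import Parameterization
from moverstayer.likelihood_onelevel import (
    AreaOutcomeSummary,
    area_path_prob,
    conditional_patient_lik,
)
from moverstayer.model_core import DataError

from conftest import (
    TOY_AREAS,
    enumerate_outcomes,
    frailty_dist,
    quadrature_marginal_onelevel,
    random_onelevel_config,
    random_patient,
)


def _simple_params(areas=TOY_AREAS, gamma=2.0, alpha=-0.5, with_pre=False):
    ap = {
        a.label: AreaParams(
            lambda0=0.4,
            beta=np.array([0.05, 0.02, 0.0]),
            theta=3.0,
            lambda0_pre=0.5 if with_pre else None,
            theta_pre=2.0 if with_pre else None,
        )
        for a in areas
    }
    st = StayerParams(alpha1={a.label: np.array([alpha]) for a in areas}, gamma=gamma)
    return ModelParams(ap, st)


class TestAreaPathProb:
    def test_single_visit_is_empty_product(self):
        p = PatientHistory(
            "s", 0.0, [0.0], {a.label: [0] for a in TOY_AREAS}
        )
        params = _simple_params()
        spec = ModelSpec(areas=TOY_AREAS)
        s = area_path_prob(p, TOY_AREAS[0], params.areas["hands"], params, spec)
        assert s.path_prob == 1.0
        assert not s.ever_damaged

    def test_all_zero_path_product_oracle(self):
        from moverstayer.model_core import truncated_nb_pmf

        p = PatientHistory(
            "z", 0.0, [0.0, 0.5, 1.2], {a.label: [0, 0, 0] for a in TOY_AREAS}
        )
        params = _simple_params()
        spec = ModelSpec(areas=TOY_AREAS)
        s = area_path_prob(p, TOY_AREAS[0], params.areas["hands"], params, spec)
        expect = 1.0
        for dt in (0.5, 0.7):
            lam = dt * 0.4  # all counts zero -> exp(0)
            expect *= truncated_nb_pmf(0, lam, 3.0, 6)
        assert s.path_prob == pytest.approx(expect, rel=1e-10)

    def test_path_prob_in_unit_interval(self):
        rng = np.random.default_rng(42)
        params = _simple_params(with_pre=True)
        spec = ModelSpec(areas=TOY_AREAS)
        for _ in range(20):
            p = random_patient(rng, with_preclinic=True)
            for a in TOY_AREAS:
                s = area_path_prob(p, a, params.areas[a.label], params, spec)
                assert 0.0 < s.path_prob <= 1.0


class TestConditionalLik:
    def test_all_damaged_read_off(self):
        sums = [
            AreaOutcomeSummary(np.log(0.3), omega=1.2, ever_damaged=True),
            AreaOutcomeSummary(np.log(0.5), omega=0.7, ever_damaged=True),
        ]
        u = 0.8
        expect = np.exp(-u * 1.2) * 0.3 * np.exp(-u * 0.7) * 0.5
        assert conditional_patient_lik(sums, u) == pytest.approx(expect, rel=1e-12)

    def test_large_u_never_damaged_factor_tends_to_one(self):
        sums = [AreaOutcomeSummary(np.log(0.3), omega=1.0, ever_damaged=False)]
        assert conditional_patient_lik(sums, 1e6) == pytest.approx(1.0, abs=1e-12)

    def test_mixed_case_scalar_oracle(self):
        sums = [
            AreaOutcomeSummary(np.log(0.4), omega=0.9, ever_damaged=False),
            AreaOutcomeSummary(np.log(0.2), omega=1.5, ever_damaged=True),
        ]
        u = 1.3
        expect = (1 - np.exp(-u * 0.9) * 0.6) * (np.exp(-u * 1.5) * 0.2)
        assert conditional_patient_lik(sums, u) == pytest.approx(expect, rel=1e-12)


class TestMarginalLik:
    def test_expansion_matches_quadrature_many_configs(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            patient, params, spec = random_onelevel_config(rng)
            closed = marginal_patient_lik(patient, params, spec)
            quad = quadrature_marginal_onelevel(patient, params, spec)
            assert closed == pytest.approx(quad, rel=1e-7)

    def test_all_damaged_single_term(self):
        params = _simple_params(gamma=1.7)
        spec = ModelSpec(areas=TOY_AREAS)
        p = PatientHistory(
            "d", 0.0, [0.0, 0.6], {a.label: [0, 1] for a in TOY_AREAS}
        )
        sums = [
            area_path_prob(p, a, params.areas[a.label], params, spec)
            for a in TOY_AREAS
        ]
        s = sum(x.omega for x in sums)
        expect = (1 + 1.7 * s) ** (-1 / 1.7) * np.prod([x.path_prob for x in sums])
        assert marginal_patient_lik(p, params, spec) == pytest.approx(expect, rel=1e-10)

    def test_tnb_variant_is_plain_product(self):
        rng = np.random.default_rng(7)
        p = random_patient(rng)
        params = _simple_params()
        spec = ModelSpec(variant="tnb", areas=TOY_AREAS)
        expect = np.prod(
            [
                area_path_prob(p, a, params.areas[a.label], params, spec).path_prob
                for a in TOY_AREAS
            ]
        )
        assert marginal_patient_lik(p, ModelParams(params.areas, None), spec) == (
            pytest.approx(expect, rel=1e-12)
        )

    def test_full_tends_to_tnb_as_alpha_to_minus_inf(self):
        rng = np.random.default_rng(13)
        pats = [random_patient(rng) for _ in range(10)]
        params_tnb = ModelParams(_simple_params().areas, None)
        params_full = _simple_params(alpha=-30.0)
        spec_full = ModelSpec(variant="full", areas=TOY_AREAS)
        spec_tnb = ModelSpec(variant="tnb", areas=TOY_AREAS)
        ll_full = dataset_loglik(pats, params_full, spec_full)
        ll_tnb = dataset_loglik(pats, params_tnb, spec_tnb)
        assert abs(ll_full - ll_tnb) < 1e-8

    def test_outcome_space_sums_to_one(self):
        for with_pre in (False, True):
            areas = tuple(
                a.__class__(a.label, 2)
                for a in TOY_AREAS  # clip capacities to 2
            )
            params = _simple_params(areas, with_pre=with_pre)
            spec = ModelSpec(areas=areas)
            total = sum(
                marginal_patient_lik(p, params, spec)
                for p in enumerate_outcomes(areas, n_visits=2, with_preclinic=with_pre)
            )
            assert total == pytest.approx(1.0, abs=1e-8)


class TestMarginalStayerProb:
    def test_logit_link_at_gamma_one(self):
        lp = np.array([-1.0, 0.0, 0.7])
        np.testing.assert_allclose(
            marginal_stayer_prob_gamma(lp, 1.0), 1 / (1 + np.exp(-lp)), rtol=1e-12
        )

    def test_cloglog_limit_small_gamma(self):
        lp = 0.0
        assert marginal_stayer_prob_gamma(lp, 1e-8) == pytest.approx(
            -np.expm1(-1.0), abs=1e-6
        )

    def test_gamma_quadrature_oracle(self):
        lp, g = 0.4, 3.9
        dist = frailty_dist(g, "gamma")
        val, _ = integrate.quad(
            lambda u: (1 - np.exp(-u * np.exp(lp))) * dist.pdf(u), 0, np.inf,
            epsabs=1e-13, limit=300,
        )
        assert marginal_stayer_prob_gamma(lp, g) == pytest.approx(val, rel=1e-9)

    def test_invgauss_limits_and_quadrature(self):
        assert marginal_stayer_prob_invgauss(-40.0, 2.0) == pytest.approx(0.0, abs=1e-12)
        assert marginal_stayer_prob_invgauss(0.3, 1e-10) == pytest.approx(
            -np.expm1(-np.exp(0.3)), abs=1e-6
        )
        lp, psi = -1.0, 2.0
        dist = frailty_dist(psi, "invgauss")
        val, _ = integrate.quad(
            lambda v: (1 - np.exp(-v * np.exp(lp))) * dist.pdf(v), 0, np.inf,
            epsabs=1e-13, limit=300,
        )
        assert marginal_stayer_prob_invgauss(lp, psi) == pytest.approx(val, rel=1e-8)

    def test_strictly_increasing_within_unit_interval(self):
        lp = np.linspace(-6, 6, 200)
        for g in (0.2, 1.0, 3.9):
            p = marginal_stayer_prob_gamma(lp, g)
            assert np.all(np.diff(p) > 0)
            assert np.all((p > 0) & (p < 1))


class TestDatasetLoglik:
    def test_additive_over_subsets(self):
        rng = np.random.default_rng(5)
        pats = [random_patient(rng) for _ in range(8)]
        params = _simple_params()
        spec = ModelSpec(areas=TOY_AREAS)
        whole = dataset_loglik(pats, params, spec)
        parts = dataset_loglik(pats[:3], params, spec) + dataset_loglik(
            pats[3:], params, spec
        )
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            dataset_loglik([], _simple_params(), ModelSpec(areas=TOY_AREAS))


class TestPackedEngine:
    @pytest.mark.parametrize(
        "variant, family", [("full", "gamma"), ("full", "invgauss"), ("tmsp", "gamma"), ("tnb", "gamma")]
    )
    def test_packed_matches_reference_and_gradient(self, variant, family):
        rng = np.random.default_rng(hash((variant, family)) % 2**31)
        pats = [random_patient(rng, with_preclinic=True) for _ in range(15)]
        spec = ModelSpec(variant=variant, frailty_u=family, areas=TOY_AREAS)
        theta = 0.0 if variant == "tmsp" else 2.5
        ap = {
            a.label: AreaParams(
                lambda0=0.4,
                beta=rng.normal(0, 0.05, 3),
                theta=theta,
                lambda0_pre=0.5,
                theta_pre=0.0 if variant == "tmsp" else 1.5,
            )
            for a in TOY_AREAS
        }
        st = None
        if variant != "tnb":
            st = StayerParams(
                alpha1={a.label: np.array([-0.4]) for a in TOY_AREAS},
                gamma=1.8 if family == "gamma" else 1.0,
                frailty_family=family,
                psi=1.8 if family == "invgauss" else None,
            )
        params = ModelParams(ap, st)
        packed = PackedData(pats, spec)
        ll, g = packed.loglik_and_grad(params)
        ll_ref = sum(marginal_patient_loglik(p, params, spec) for p in pats)
        assert ll == pytest.approx(ll_ref, rel=1e-10)

        par = Parameterization(spec, packed.has_preclinic)
        x = par.pack(params)
        for i in range(len(x)):
            h = 1e-6 * max(1.0, abs(x[i]))
            e = np.zeros_like(x)
            e[i] = h
            fd = (packed.loglik(par.unpack(x + e)) - packed.loglik(par.unpack(x - e))) / (
                2 * h
            )
            assert g[i] == pytest.approx(fd, rel=2e-5, abs=1e-6), par.names[i]
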