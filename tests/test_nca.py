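"""Tests of the noncompartmental estimator against analytic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gdnca.nca import (
    NotEvaluableError,
    back_extrapolate_c0,
    derive_parameters,
    extrapolate_to_infinity,
    find_cmax_tmax,
    fit_lambda_z,
    integrate_auc_aumc,
    run_nca,
    run_nca_cohort,
    trapezoid_linear,
    trapezoid_log,
)
from gdnca.simulate import (
    CohortConfig,
    DispositionParams,
    ValidationError,
    macro_from_micro,
    simulate_cohort,
)

from .conftest import dense_log_times, make_profile, mono_profile


class TestCmaxTmax:
    @pytest.mark.parametrize(
        "concs, expected",
        [
            ([300.0, 150.0, 80.0], (300.0, 1.0)),
            ([100.0, 100.0, 50.0], (100.0, 1.0)),  # tie -> earliest time
        ],
    )
    def test_observed_peak(self, concs, expected):
        profile = make_profile([1.0, 3.0, 5.0], concs)
        assert find_cmax_tmax(profile) == expected

    def test_monotone_decay_peaks_at_first_sample(self):
        profile = mono_profile(200.0, 0.1, [1, 3, 5, 10, 20])
        cmax, tmax = find_cmax_tmax(profile)
        assert tmax == 1.0
        assert cmax == pytest.approx(200.0 * math.exp(-0.1))

    def test_all_blq_not_evaluable(self):
        profile = make_profile([1, 3, 5], [1, 1, 1], blq=[True, True, True])
        with pytest.raises(NotEvaluableError, match="all_blq"):
            find_cmax_tmax(profile)


class TestBackExtrapolation:
    def test_log_linear_through_first_two_points(self):
        profile = make_profile([1.0, 3.0, 5.0], [100.0, 25.0, 10.0])
        c0, fallback = back_extrapolate_c0(profile)
        assert not fallback
        assert c0 == pytest.approx(200.0, rel=1e-12)  # 100·exp(ln4/2)

    def test_non_decreasing_start_falls_back_to_first_observation(self):
        profile = make_profile([1.0, 3.0, 5.0], [50.0, 50.0, 20.0])
        c0, fallback = back_extrapolate_c0(profile)
        assert fallback and c0 == 50.0

    def test_exact_on_mono_exponential(self):
        profile = mono_profile(123.4, 0.07, [1, 3, 5, 10])
        c0, fallback = back_extrapolate_c0(profile)
        assert not fallback
        assert c0 == pytest.approx(123.4, rel=1e-9)


class TestTrapezoids:
    @pytest.mark.parametrize(
        "c1, c2, dt, expected",
        [(10.0, 10.0, 1.0, 10.0), (0.0, 10.0, 2.0, 10.0), (238.1, 100.0, 2.0, 338.1)],
    )
    def test_linear(self, c1, c2, dt, expected):
        assert trapezoid_linear(c1, c2, dt) == pytest.approx(expected)

    def test_log_formula(self):
        assert trapezoid_log(10.0, 5.0, 1.0) == pytest.approx(5.0 / math.log(2.0))

    @given(
        c0=st.floats(1.0, 500.0),
        lam=st.floats(0.005, 0.5),
        t1=st.floats(0.0, 50.0),
        dt=st.floats(0.5, 40.0),
    )
    def test_log_rule_exact_on_exponentials(self, c0, lam, t1, dt):
        """The log trapezoid integrates a pure exponential segment exactly."""
        c1 = c0 * math.exp(-lam * t1)
        c2 = c0 * math.exp(-lam * (t1 + dt))
        exact = (c1 - c2) / lam
        assert trapezoid_log(c1, c2, dt) == pytest.approx(exact, rel=1e-12)

    @pytest.mark.parametrize("c1, c2", [(10.0, 10.0), (0.0, 5.0), (5.0, 0.0)])
    def test_log_rejects_degenerate_endpoints(self, c1, c2):
        with pytest.raises(ValidationError):
            trapezoid_log(c1, c2, 1.0)

    def test_linear_rejects_nonpositive_dt(self):
        with pytest.raises(ValidationError):
            trapezoid_linear(1.0, 1.0, 0.0)


class TestIntegration:
    def test_flat_profile_uses_linear_rule_with_flag(self):
        profile = make_profile([1.0, 2.0, 3.0], [10.0, 10.0, 10.0])
        auc, aumc, flags = integrate_auc_aumc(profile, 10.0)
        assert auc == pytest.approx(30.0)
        assert "flat_segment_linear" in flags

    def test_dense_biexponential_matches_closed_form(self):
        a_coef, alpha, b_coef, beta = 200.0, 0.3, 50.0, 0.02
        t = dense_log_times(alpha, beta, n=8000, n_halves=8.0)
        c = a_coef * np.exp(-alpha * t) + b_coef * np.exp(-beta * t)
        profile = make_profile(t, c)
        auc, aumc, _ = integrate_auc_aumc(profile, a_coef + b_coef)
        T = t[-1]
        auc_exact = a_coef * (1 - np.exp(-alpha * T)) / alpha + b_coef * (
            1 - np.exp(-beta * T)
        ) / beta
        # ∫ t·e^{-kt} dt = (1 - e^{-kT}(1 + kT)) / k²
        aumc_exact = sum(
            coef * (1 - np.exp(-k * T) * (1 + k * T)) / k**2
            for coef, k in ((a_coef, alpha), (b_coef, beta))
        )
        assert auc == pytest.approx(auc_exact, rel=1e-6)
        assert aumc == pytest.approx(aumc_exact, rel=1e-5)

    def test_too_few_points_not_evaluable(self):
        profile = make_profile([1.0, 2.0], [10.0, 5.0])
        with pytest.raises(NotEvaluableError, match="lt_3_quantifiable"):
            integrate_auc_aumc(profile, 12.0)


class TestLambdaZ:
    def test_exact_log_linear_data(self):
        profile = make_profile(
            [1.0, 30.0, 60.0, 90.0],
            [100.0, *(100.0 * np.exp(-0.05 * np.array([30.0, 60.0, 90.0])))],
        )
        fit = fit_lambda_z(profile)
        assert fit.lambda_z == pytest.approx(0.05, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.c_last_pred == pytest.approx(100.0 * math.exp(-4.5), rel=1e-9)

    def test_half_life_identity(self):
        t = np.array([1.0, 10.0, 20.0, 30.0])
        profile = make_profile(t, 10.0 * np.exp(-math.log(2.0) * t))
        result = run_nca(profile)
        assert result.t_half_beta == pytest.approx(1.0, rel=1e-9)

    def test_terminal_slope_of_biexponential_near_beta(self):
        """With α ≫ β the terminal window recovers β within 1%."""
        from gdnca.simulate import micro_from_macro

        a_coef, alpha, b_coef, beta = 200.0, 0.6, 50.0, 0.02  # α/β = 30
        params = micro_from_macro(a_coef, alpha, b_coef, beta, 30.0)
        t = np.array([1.0, 3.0, 5.0, 10.0, 20.0, 30.0, 60.0, 90.0])
        from gdnca.simulate import biexponential_concentration

        profile = make_profile(t, biexponential_concentration(params, 30.0, t))
        fit = fit_lambda_z(profile)
        assert fit.lambda_z == pytest.approx(beta, rel=0.01)

    def test_fixed_window_override(self):
        t = np.array([1.0, 3.0, 30.0, 60.0, 90.0])
        profile = make_profile(t, 100.0 * np.exp(-0.04 * t))
        fit = fit_lambda_z(profile, window=(30.0, 90.0))
        assert fit.n_points == 3
        assert fit.time_range == (30.0, 90.0)
        assert fit.lambda_z == pytest.approx(0.04, rel=1e-10)

    def test_rising_tail_not_evaluable(self):
        profile = make_profile([1, 10, 20, 30, 40], [100, 5, 6, 7, 8])
        with pytest.raises(NotEvaluableError, match="no_terminal_decline"):
            fit_lambda_z(profile)


class TestExtrapolation:
    def test_mono_exponential_tail_is_exact(self):
        c0, lam = 100.0, 0.05
        t = np.array([1.0, 10.0, 30.0, 60.0, 90.0])
        profile = mono_profile(c0, lam, t)
        fit = fit_lambda_z(profile)
        auc_last, aumc_last, _ = integrate_auc_aumc(profile, c0)
        auc_inf, _, pct, _ = extrapolate_to_infinity(auc_last, aumc_last, fit, None, 90.0)
        assert auc_inf == pytest.approx(c0 / lam, rel=1e-10)
        assert pct == pytest.approx(100.0 * (1 - auc_last / auc_inf))

    def test_large_extrapolation_is_flagged_not_rejected(self):
        c0, lam = 100.0, 0.002  # slow decline -> large extrapolated fraction
        t = np.array([1.0, 10.0, 30.0, 60.0, 90.0])
        profile = mono_profile(c0, lam, t)
        result = run_nca(profile)
        assert result.auc_extrapolated_pct > 20.0
        assert "extrapolation_gt_20pct" in result.quality_flags


class TestDerivedParameters:
    def test_clearance_unit_arithmetic(self):
        fit = run_nca(mono_profile(100.0, 0.05, np.array([1, 10, 30, 60, 90.0]))).lambda_z_fit
        out = derive_parameters(3000.0, 60000.0, fit, 30.0)
        assert out["cl"] == pytest.approx(10.0)  # 30/3000 L/min = 10 mL/min
        assert out["mrt"] == pytest.approx(20.0)
        assert out["v_ss"] == pytest.approx(out["cl"] * out["mrt"])

    def test_zero_dose_rejected(self):
        fit = run_nca(mono_profile(100.0, 0.05, np.array([1, 10, 30, 60, 90.0]))).lambda_z_fit
        with pytest.raises(ValidationError):
            derive_parameters(3000.0, 60000.0, fit, 0.0)


class TestRunNCA:
    def test_one_compartment_closure(self):
        """Every NCA output matches the mono-exponential closed form."""
        dose, c0, lam = 30.0, 300.0, 0.05
        t = dense_log_times(lam, lam, n=6000)
        result = run_nca(mono_profile(c0, lam, t, dose=dose))
        v = 1000.0 * dose / c0  # mL
        assert result.cl == pytest.approx(lam * v, rel=1e-6)
        assert result.v_z == pytest.approx(v, rel=1e-6)
        assert result.v_ss == pytest.approx(v, rel=1e-6)
        assert result.mrt == pytest.approx(1.0 / lam, rel=1e-6)
        assert result.t_half_beta == pytest.approx(math.log(2.0) / lam, rel=1e-9)

    def test_biexponential_mrt_closed_form(self):
        params = DispositionParams(8.0, 90.0, 160.0, 10.0)
        a_coef, alpha, b_coef, beta = macro_from_micro(params, 30.0)
        t = dense_log_times(alpha, beta, n=12000, n_halves=15.0)
        c = a_coef * np.exp(-alpha * t) + b_coef * np.exp(-beta * t)
        result = run_nca(make_profile(t, c))
        mrt_true = (a_coef / alpha**2 + b_coef / beta**2) / (
            a_coef / alpha + b_coef / beta
        )
        assert result.mrt == pytest.approx(mrt_true, rel=1e-4)
        # MRT of the two-compartment model is Vss/CL
        assert result.mrt == pytest.approx(params.v_ss / params.clearance_total, rel=1e-4)

    def test_all_blq_is_structured_failure(self):
        profile = make_profile([1, 3, 5], [1, 1, 1], blq=[True, True, True])
        with pytest.raises(NotEvaluableError) as err:
            run_nca(profile)
        assert err.value.reason == "all_blq"

    def test_definitional_identities_on_simulated_cohort(self):
        params, failures = run_nca_cohort(simulate_cohort(CohortConfig(seed=4)))
        assert failures.empty
        np.testing.assert_allclose(
            params["auc_extrapolated_pct"],
            100.0 * (1.0 - params["auc_last"] / params["auc_inf"]),
            rtol=1e-12,
        )
        np.testing.assert_allclose(params["v_ss"], params["cl"] * params["mrt"], rtol=1e-12)
        np.testing.assert_allclose(params["t_half_eff"], 0.693 * params["mrt"], rtol=1e-12)
        assert (params["auc_inf"] >= params["auc_last"]).all()
        assert (params[["cl", "v_ss", "v_z", "mrt", "t_half_beta"]] > 0).all().all()

    @pytest.mark.parametrize("scale", [2.0, 0.25])
    def test_concentration_scaling(self, scale):
        """Scaling all concentrations by k divides CL by k; half-lives unchanged."""
        t = np.array([1, 3, 5, 10, 20, 30, 60, 90.0])
        base = make_profile(t, 200.0 * np.exp(-0.1 * t) + 60.0 * np.exp(-0.02 * t))
        scaled = make_profile(t, scale * base.concentrations)
        r0, r1 = run_nca(base), run_nca(scaled)
        assert r1.cl == pytest.approx(r0.cl / scale, rel=1e-9)
        assert r1.t_half_beta == pytest.approx(r0.t_half_beta, rel=1e-12)
        assert r1.t_half_eff == pytest.approx(r0.t_half_eff, rel=1e-9)

    def test_dose_scaling(self):
        """Doubling dose at fixed concentrations doubles CL and the volumes."""
        t = np.array([1, 3, 5, 10, 20, 30, 60, 90.0])
        profile = make_profile(t, 200.0 * np.exp(-0.1 * t) + 60.0 * np.exp(-0.02 * t))
        r1 = run_nca(profile, dose=30.0)
        r2 = run_nca(profile, dose=60.0)
        for attr in ("cl", "v_ss", "v_z"):
            assert getattr(r2, attr) == pytest.approx(2.0 * getattr(r1, attr), rel=1e-12)

    def test_group_mean_cl_recovery(self):
        """Sample-mean CL per group lands within 2 SEM of the generative mean."""
        config = CohortConfig(seed=12)
        params, _ = run_nca_cohort(simulate_cohort(config))
        for gi, group in enumerate(config.groups):
            mean_cl = params.loc[params.group == group, "cl"].mean()
            truth = config.group_clearance_means[gi]
            sem = truth * config.between_subject_cv[gi] / math.sqrt(config.group_sizes[gi])
            assert abs(mean_cl - truth) < 2.0 * sem

    def test_cohort_with_all_blq_subject_yields_failure_record(self):
        profiles = list(simulate_cohort(CohortConfig(seed=6, group_sizes=(3, 2, 2))))
        bad = make_profile([1, 3, 5], [1, 1, 1], blq=[True] * 3, subject_id="bad")
        params, failures = run_nca_cohort(profiles + [bad])
        assert len(params) == len(profiles)
        assert len(failures) == 1
        assert failures.iloc[0]["reason"] == "all_blq"
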