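"""Estimators: dwell-time fits, enzymology, binding, poisoning, stall geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helifret import (AT40, GC1, GC2, GC3, binding_model, competitive_km,
                      fit_binding_titration, fit_exponential_lifetime,
                      fit_gamma_step_size, fit_hill, fit_ki,
                      fit_michaelis_menten, fit_poison_model, fit_stall_levels,
                      poison_stall_probability, predict_stall_positions)
from helifret.fits import _hill_model, _mm_model


class TestGammaStepSize:
    def test_exponential_times_give_single_step(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(0.5, size=2000)
        fit = fit_gamma_step_size(times, n_bp=40, n_boot=50)
        assert fit.kinetic_step_size == pytest.approx(40.0, rel=0.1)

    def test_erlang_shape_10_gives_4bp_step(self):
        rng = np.random.default_rng(1)
        times = rng.gamma(shape=10, scale=0.05, size=2000)
        fit = fit_gamma_step_size(times, n_bp=40, n_boot=50)
        assert abs(fit.kinetic_step_size - 4.0) <= 0.3
        lo, hi = fit.step_size_ci
        assert lo <= 4.0 <= hi

    def test_heterogeneity_inflates_step_size(self):
        # 40 identical steps, but per-molecule rates vary: the broadened
        # distribution mimics fewer, larger steps
        rng = np.random.default_rng(2)
        rates = rng.gamma(shape=4, scale=76.4 / 4, size=2000)
        times = rng.gamma(shape=40, scale=1.0, size=2000) / rates
        fit = fit_gamma_step_size(times, n_bp=40, n_boot=50)
        assert fit.kinetic_step_size > 1.2

    def test_invariant_to_time_rescaling(self):
        rng = np.random.default_rng(3)
        times = rng.gamma(shape=8, scale=0.1, size=500)
        a = fit_gamma_step_size(times, n_bp=40, n_boot=20)
        b = fit_gamma_step_size(3.0 * times, n_bp=40, n_boot=20)
        assert a.n_steps == pytest.approx(b.n_steps, rel=1e-4)
        assert a.kinetic_step_size == pytest.approx(b.kinetic_step_size, rel=1e-4)

    def test_small_samples_refused(self):
        with pytest.raises(ValueError):
            fit_gamma_step_size(np.ones(10), n_bp=40)


class TestExponentialLifetime:
    def test_degenerate_constant_sample(self):
        fit = fit_exponential_lifetime(np.full(12, 0.3))
        assert fit.tau == pytest.approx(0.3)
        assert fit.ci == pytest.approx((0.3, 0.3))

    def test_poison_stall_lifetime_recovered(self):
        rng = np.random.default_rng(4)
        draws = rng.exponential(0.44, size=5000)
        fit = fit_exponential_lifetime(draws, seed=5)
        se = 0.44 / np.sqrt(len(draws))
        assert abs(fit.tau - 0.44) < 3 * se

    def test_mle_equals_arithmetic_mean(self):
        rng = np.random.default_rng(6)
        draws = rng.exponential(1.7, size=64)
        assert fit_exponential_lifetime(draws).tau == np.mean(draws)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_lifetime([])

    def test_bootstrap_ci_coverage(self):
        # nominal 95% interval must cover the true mean in >= 90% of replicates
        rng = np.random.default_rng(7)
        hits = 0
        for i in range(200):
            draws = rng.exponential(0.44, size=50)
            fit = fit_exponential_lifetime(draws, n_boot=300, seed=i)
            hits += fit.ci[0] <= 0.44 <= fit.ci[1]
        assert hits >= 180


class TestStallLevelMixture:
    def test_single_peak(self):
        rng = np.random.default_rng(8)
        levels = 0.48 + rng.normal(0, 0.02, 200)
        fit = fit_stall_levels(levels)
        assert fit.n_components == 1
        assert fit.means[0] == pytest.approx(0.48, abs=0.01)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(9)
        levels = np.concatenate([0.48 + rng.normal(0, 0.03, 200),
                                 0.35 + rng.normal(0, 0.03, 200)])
        fit = fit_stall_levels(levels)
        assert fit.n_components == 2
        assert fit.means[0] == pytest.approx(0.48, abs=0.02)
        assert fit.means[1] == pytest.approx(0.35, abs=0.02)
        assert sum(fit.weights) == pytest.approx(1.0)

    def test_fixed_component_count_override(self):
        rng = np.random.default_rng(10)
        levels = 0.5 + rng.normal(0, 0.02, 100)
        fit = fit_stall_levels(levels, n_components=2, min_separation=0.0)
        assert fit.n_components == 2

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_stall_levels(np.full(10, 0.5))


class TestMichaelisMenten:
    ATP = np.array([25.0, 50.0, 87.0, 150.0, 300.0, 750.0, 1500.0, 3000.0])

    def test_rate_at_km_is_half_maximal(self):
        v = _mm_model(self.ATP, 1.91, 87.0)
        fit = fit_michaelis_menten(self.ATP, v)
        assert _mm_model(fit.K_M, fit.k_max, fit.K_M) == pytest.approx(
            fit.k_max / 2)
        assert fit.K_M == pytest.approx(87.0, rel=1e-6)

    def test_recovery_with_noise_within_ci(self):
        rng = np.random.default_rng(11)
        v = _mm_model(self.ATP, 1.91, 87.0) * (1 + rng.normal(0, 0.03, len(self.ATP)))
        fit = fit_michaelis_menten(self.ATP, v)
        assert abs(fit.K_M - 87.0) < 2.5 * fit.K_M_se
        assert abs(fit.k_max - 1.91) < 2.5 * fit.k_max_se

    def test_ci_coverage_over_replicates(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(200):
            v = _mm_model(self.ATP, 1.91, 87.0) * (
                1 + rng.normal(0, 0.03, len(self.ATP)))
            fit = fit_michaelis_menten(self.ATP, v)
            hits += abs(fit.K_M - 87.0) < 1.96 * fit.K_M_se
        assert hits >= 180

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten([100.0, 100.0, 100.0, 100.0], [1, 1, 1, 1])


class TestHill:
    ATP = TestMichaelisMenten.ATP

    def test_mm_data_gives_unit_hill_coefficient(self):
        rng = np.random.default_rng(13)
        v = _mm_model(self.ATP, 1.91, 87.0) * (1 + rng.normal(0, 0.03, len(self.ATP)))
        fit = fit_hill(self.ATP, v)
        assert abs(fit.hill_n - 1.0) < 2.5 * fit.hill_n_se

    def test_nested_model_never_fits_worse(self):
        rng = np.random.default_rng(14)
        v = _mm_model(self.ATP, 1.91, 87.0) * (1 + rng.normal(0, 0.02, len(self.ATP)))
        mm = fit_michaelis_menten(self.ATP, v)
        hill = fit_hill(self.ATP, v)
        ssr_mm = np.sum((v - _mm_model(self.ATP, mm.k_max, mm.K_M)) ** 2)
        ssr_hill = np.sum((v - _hill_model(self.ATP, hill.k_max, hill.K_M,
                                           hill.hill_n)) ** 2)
        assert ssr_hill <= ssr_mm + 1e-10

    def test_cooperative_data_recovered(self):
        rng = np.random.default_rng(15)
        v = _hill_model(self.ATP, 1.91, 87.0, 2.0) * (
            1 + rng.normal(0, 0.03, len(self.ATP)))
        fit = fit_hill(self.ATP, v)
        assert abs(fit.hill_n - 2.0) < 2.5 * fit.hill_n_se

    def test_half_maximal_rate_at_fitted_khalf(self):
        v = _hill_model(self.ATP, 1.91, 87.0, 1.2)
        fit = fit_hill(self.ATP, v)
        assert _hill_model(fit.K_M, fit.k_max, fit.K_M, fit.hill_n) == \
            pytest.approx(fit.k_max / 2)


class TestCompetitiveInhibition:
    def test_no_inhibitor_leaves_km(self):
        assert competitive_km(87.0, 418.3, 0.0) == 87.0

    def test_ki_from_printed_values(self):
        assert fit_ki(87.0, 191.0, 500.0) == pytest.approx(418.3, abs=0.5)

    def test_predicted_1mM_apparent_km_inside_printed_error(self):
        ki = fit_ki(87.0, 191.0, 500.0)
        km_app = competitive_km(87.0, ki, 1000.0)
        assert km_app == pytest.approx(295.0, abs=1.0)
        assert 272.0 - 36.0 <= km_app <= 272.0 + 36.0

    @given(st.floats(10.0, 500.0), st.floats(50.0, 5000.0), st.floats(1.0, 5000.0))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_identity(self, km, ki, inhibitor):
        km_app = competitive_km(km, ki, inhibitor)
        assert fit_ki(km, km_app, inhibitor) == pytest.approx(ki, rel=1e-9)

    def test_non_inhibitory_data_rejected(self):
        with pytest.raises(ValueError):
            fit_ki(87.0, 80.0, 500.0)


class TestBindingTitration:
    L = np.array([0.25, 0.5, 1.0, 2.0, 3.5, 7.0, 15.0, 30.0, 60.0])

    def test_infinite_kd_limit_is_flat_f0(self):
        f = binding_model(self.L, 100.0, -60.0, 1e9, E_tot=1.0)
        np.testing.assert_allclose(f, 100.0, atol=1e-5)

    def test_kd_recovery_ci_coverage(self):
        # unbiased recovery of K_D = 3.5 µM at titration-scale noise, with
        # nominal CI coverage over replicates
        kds, hits = [], 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            f = binding_model(self.L, 100.0, -60.0, 3.5, E_tot=1.0)
            f = f + rng.normal(0, 0.3, len(f))
            fit = fit_binding_titration(self.L, f, E_tot=1.0)
            kds.append(fit.K_D)
            hits += abs(fit.K_D - 3.5) < 2.5 * fit.K_D_se
        assert hits >= 90
        assert np.mean(kds) == pytest.approx(3.5, rel=0.1)

    def test_complex_concentration_matches_quadratic_roots(self):
        # independent oracle: solve the binding quadratic numerically
        for e_tot, l_tot, kd in [(3.5, 3.5, 3.5), (1.0, 5.0, 2.0), (2.0, 0.5, 10.0)]:
            roots = np.roots([1.0, -(e_tot + l_tot + kd), e_tot * l_tot])
            el = min(r.real for r in roots if 0 <= r.real <= min(e_tot, l_tot) + 1e-12)
            expected = 7.0 + 5.0 * el / l_tot
            got = binding_model(l_tot, 7.0, 5.0, kd, E_tot=e_tot)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_binding_titration([1, 2, 3], [1, 2, 3], E_tot=1.0)


class TestPoisonModel:
    def test_offset_only_when_no_atpgs(self):
        res = poison_stall_probability(1000.0, 0.0, 87.0, 1.4, p_offset=0.07)
        assert res.p_stall == pytest.approx(0.07)
        assert res.alpha == 1.0

    def test_worked_arithmetic_example(self):
        res = poison_stall_probability(990.0, 10.0, 87.0, 1.4)
        assert res.alpha == pytest.approx(8.142857, rel=1e-6)
        assert res.K_M_app == pytest.approx(8.142857 * 87.0, rel=1e-6)
        assert res.f_bound == pytest.approx(0.5829, abs=2e-4)
        assert 1 - res.f_bound ** 6 == pytest.approx(0.961, abs=2e-3)

    def test_matches_monte_carlo_lottery(self):
        # brute-force six independent site lotteries, 1e6 hexamers, with and
        # without ATPgS: the ATPgS-attributable excess plus an independent
        # baseline-stall draw reproduces p_stall
        atp, atpgs, km, kd, p_off = 990.0, 5.0, 87.0, 1.4, 0.05
        res = poison_stall_probability(atp, atpgs, km, kd, p_offset=p_off)
        rng = np.random.default_rng(17)
        n = 1_000_000
        f0 = atp / (km + atp)
        missing = ~(rng.random((n, 6)) < res.f_bound).all(axis=1)
        missing0 = ~(rng.random((n, 6)) < f0).all(axis=1)
        excess_mc = np.mean(missing) - np.mean(missing0)
        offset_draw = rng.random(n) < p_off
        p_mc = np.mean(offset_draw) + (1 - np.mean(offset_draw)) * excess_mc
        se = np.sqrt(2.0 / n)   # conservative for the difference of two means
        assert abs(res.p_stall - p_mc) < 3 * se

    def test_near_linear_in_atpgs_at_low_mixes(self):
        # below K_D the poisoning term is first order in [ATPgS]
        atpgs = np.array([0.125, 0.25, 0.5, 0.75, 1.0])   # µM, ~< K_D
        p = np.array([
            poison_stall_probability(1000.0 - g, g, 87.0, 1.4,
                                     p_offset=0.05).p_stall
            for g in atpgs])
        resid = p - 0.05
        r = np.corrcoef(atpgs, resid)[0, 1]
        assert r ** 2 > 0.98
        assert np.all(np.diff(p) > 0)

    def test_offset_recovery_from_forward_model(self):
        rng = np.random.default_rng(18)
        fracs = np.array([0.00125, 0.0025, 0.005, 0.0075, 0.01, 0.025])
        truth = np.array([
            poison_stall_probability((1 - f) * 1000, f * 1000, 87.0, 1.4,
                                     p_offset=0.10).p_stall for f in fracs])
        observed = np.clip(truth + rng.normal(0, 0.01, len(fracs)), 0, 1)
        _, p_off, se = fit_poison_model(fracs, observed, K_M=87.0, K_D=1.4)
        assert abs(p_off - 0.10) < 0.03

    def test_zero_offset_ci_includes_zero(self):
        fracs = np.array([0.00125, 0.0025, 0.005, 0.01])
        truth = np.array([
            poison_stall_probability((1 - f) * 1000, f * 1000, 87.0, 1.4,
                                     p_offset=0.0).p_stall for f in fracs])
        _, p_off, se = fit_poison_model(fracs, truth, K_M=87.0, K_D=1.4)
        assert p_off - 1.96 * max(se, 1e-9) <= 1e-6

    def test_stall_fraction_monotone_in_mix(self):
        lo = poison_stall_probability(999.0, 1.0, 87.0, 1.4, p_offset=0.05)
        hi = poison_stall_probability(990.0, 10.0, 87.0, 1.4, p_offset=0.05)
        assert hi.p_stall > lo.p_stall

    def test_no_nucleotide_warns(self):
        with pytest.warns(UserWarning):
            res = poison_stall_probability(0.0, 0.0, 87.0, 1.4)
        assert res.f_bound == 0.0


class TestPredictedStallPositions:
    def test_one_gc_one_level_for_1bp_two_for_2bp(self):
        assert len(predict_stall_positions(GC1, 1)) == 1
        assert len(predict_stall_positions(GC1, 2)) == 2

    def test_two_gc(self):
        assert [p for p, _ in predict_stall_positions(GC2, 1)] == [10, 11]
        assert [p for p, _ in predict_stall_positions(GC2, 2)] == [9, 10, 11]

    def test_three_gc(self):
        assert [p for p, _ in predict_stall_positions(GC3, 1)] == [10, 11, 12]
        assert len(predict_stall_positions(GC3, 2)) == 4

    def test_no_gc_no_stalls(self):
        assert predict_stall_positions(AT40, 1) == []
        assert predict_stall_positions(AT40, 2) == []

    def test_levels_follow_calibration(self):
        levels = dict(predict_stall_positions(GC3, 1))
        assert levels[10] == pytest.approx(0.48)
        assert levels[11] == pytest.approx(0.40, abs=1e-9)
        assert levels[12] == pytest.approx(0.32, abs=1e-9)

    def test_unsupported_step_size_rejected(self):
        with pytest.raises(ValueError):
            predict_stall_positions(GC1, 3)
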