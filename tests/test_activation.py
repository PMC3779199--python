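"""Progress-curve kinetics, Michaelis-Menten depletion, species network."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from zymokin import activation as act
from zymokin import synthetic


class TestProgressModel:
    def test_zero_at_time_zero(self):
        assert act.progress_value(0.0, 0.0005, 0.005, 0.0035) == 0.0

    def test_small_k_limit_is_initial_rate(self):
        t = np.array([100.0, 900.0])
        np.testing.assert_allclose(act.progress_value(t, 0.0005, 0.005, 0.0),
                                   0.0005 * t)
        np.testing.assert_allclose(
            act.progress_value(t, 0.0005, 0.005, 1e-10), 0.0005 * t, rtol=1e-6)

    def test_large_k_limit_is_steady_state_rate(self):
        t = np.array([100.0, 900.0])
        np.testing.assert_allclose(act.progress_value(t, 0.0005, 0.005, 1e4),
                                   0.005 * t, rtol=1e-5)

    def test_frozen_scalar_value(self):
        # frozen from direct scalar evaluation of the lag/burst expression
        val = act.progress_value(600.0, 0.0005, 0.005, 0.0035)
        assert val == pytest.approx(1.8717296934681193, rel=1e-12)

    def test_initial_slope_is_vi_and_asymptotic_slope_is_vs(self):
        vi, vs, k = 0.0005, 0.005, 0.0035
        eps = 1e-6
        d0 = act.progress_value(eps, vi, vs, k) / eps
        assert d0 == pytest.approx(vi, rel=1e-4)
        t = 1e7
        dinf = ((act.progress_value(t + 1, vi, vs, k)
                 - act.progress_value(t, vi, vs, k)))
        assert dinf == pytest.approx(vs, rel=1e-6)


class TestFitProgress:
    def test_noise_free_exact_recovery(self):
        truth = act.ProgressFit(v_i=0.0005, v_s=0.005, k_obs=0.0035)
        curve = synthetic.simulate_progress_curve(truth, noise_rel=0.0)
        fit = act.fit_progress(curve)
        assert fit.k_obs == pytest.approx(0.0035, rel=1e-6)
        assert fit.v_i == pytest.approx(0.0005, rel=1e-5)
        assert fit.v_s == pytest.approx(0.005, rel=1e-6)

    @pytest.mark.parametrize("k_true", [0.0035, 0.0011])
    def test_noisy_mean_recovery_within_five_percent(self, k_true):
        truth = act.ProgressFit(v_i=0.0005, v_s=0.005, k_obs=k_true)
        fits = [act.fit_progress(synthetic.simulate_progress_curve(
            truth, noise_rel=0.01, seed=s)).k_obs for s in range(30)]
        assert np.mean(fits) == pytest.approx(k_true, rel=0.05)

    def test_recovery_invariant_to_rate_scale(self):
        # k_obs estimate should not depend on the (v_i, v_s) scale
        for scale in (0.1, 10.0):
            truth = act.ProgressFit(v_i=0.0005 * scale, v_s=0.005 * scale,
                                    k_obs=0.0035)
            curve = synthetic.simulate_progress_curve(truth, noise_rel=0.01,
                                                      seed=11)
            assert act.fit_progress(curve).k_obs == pytest.approx(
                0.0035, rel=0.05)

    def test_short_curve_warns(self):
        truth = act.ProgressFit(v_i=0.0005, v_s=0.005, k_obs=0.0005)
        curve = synthetic.simulate_progress_curve(
            truth, duration_s=600.0, noise_rel=0.0)
        with pytest.warns(UserWarning, match="3/k_obs"):
            act.fit_progress(curve)

    def test_deactivation_warns(self):
        truth = act.ProgressFit(v_i=0.005, v_s=0.0005, k_obs=0.0035)
        curve = synthetic.simulate_progress_curve(truth, noise_rel=0.0)
        with pytest.warns(UserWarning, match="no activation"):
            act.fit_progress(curve)


class TestKobsLinear:
    def test_exact_line_recovered(self):
        e1 = np.array([0.0, 0.0005, 0.001, 0.0015])
        series = act.ActivatorSeries(e1, 2.5 * e1)
        slope, intercept, _ = act.fit_kobs_linear(series)
        assert slope == pytest.approx(2.5)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_permutation_and_duplicates_allowed(self):
        e1 = np.array([0.001, 0.0, 0.001, 0.0005])
        y = 2.5 * e1 + 1e-4
        s1 = act.fit_kobs_linear(act.ActivatorSeries(e1, y))
        order = np.argsort(e1)
        s2 = act.fit_kobs_linear(act.ActivatorSeries(e1[order], y[order]))
        assert s1[0] == pytest.approx(s2[0])
        assert s1[1] == pytest.approx(s2[1])

    def test_noisy_slope_within_ten_percent(self):
        rng = np.random.default_rng(42)
        e1 = np.array([0.0, 0.00025, 0.0005, 0.001, 0.0015])
        y = 2.5 * e1 * (1 + rng.normal(0, 0.02, e1.size))
        # oracle: closed-form OLS on the generated points
        A = np.vander(e1, 2)
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        slope, intercept, se = act.fit_kobs_linear(act.ActivatorSeries(e1, y))
        assert slope == pytest.approx(beta[0], rel=1e-10)
        assert slope == pytest.approx(2.5, rel=0.10)
        assert np.isfinite(se["slope"])

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            act.fit_kobs_linear(act.ActivatorSeries([0.0, 1.0], [0.0, 1.0]))


def mm_params(**kw):
    base = dict(km_uM=4.5, kcat_per_s=0.095, activator_uM=0.16, z0_uM=16.0)
    base.update(kw)
    return act.MMActivationParams(**base)


class TestMMDepletion:
    def test_ode_matches_closed_form_to_1e6(self):
        p = mm_params()
        t = np.linspace(0.0, 2400.0, 2000)
        ode = act.mm_depletion(p, t, method="ode")
        cf = act.mm_depletion(p, t, method="closed_form")
        rel = np.abs(ode.zymogen - cf.zymogen) / np.maximum(cf.zymogen, 1e-9)
        assert rel.max() < 1e-6

    def test_closed_form_matches_implicit_equation_root(self):
        # oracle: root-finding on K_m ln(Z0/Z) + (Z0 - Z) = kcat E1 t
        p = mm_params()
        for t, expected in [(300.0, 12.537419465925707),
                            (600.0, 9.31454974944194),
                            (1200.0, 3.999211629389836),
                            (2400.0, 0.16288370992189702)]:
            def implicit(z):
                return (p.km_uM * np.log(p.z0_uM / z) + p.z0_uM - z
                        - p.kcat_per_s * p.activator_uM * t)
            root = brentq(implicit, 1e-12, p.z0_uM, xtol=1e-14)
            got = act.integrated_mm_zymogen(t, p)
            assert root == pytest.approx(expected, rel=1e-10)
            assert got == pytest.approx(root, rel=1e-10)

    def test_first_order_limit_when_km_dominates(self):
        p = mm_params(km_uM=5000.0)
        t = np.linspace(0.0, 2400.0, 200)
        tc = act.mm_depletion(p, t, method="closed_form")
        rate = p.kcat_per_s * p.activator_uM / p.km_uM
        np.testing.assert_allclose(tc.zymogen, 16.0 * np.exp(-rate * t),
                                   rtol=1e-2)

    def test_zero_order_limit_when_saturated(self):
        p = mm_params(km_uM=0.001)
        t = np.linspace(0.0, 100.0, 50)
        tc = act.mm_depletion(p, t, method="closed_form")
        np.testing.assert_allclose(
            tc.zymogen, 16.0 - p.kcat_per_s * p.activator_uM * t, rtol=1e-3)

    def test_mass_closure_with_autolysis_sinks(self):
        p = mm_params(k_auto_per_s=1e-4, k_deg_per_s=5e-5)
        t = np.linspace(0.0, 2400.0, 300)
        tc = act.mm_depletion(p, t, method="ode")
        total = tc.zymogen + tc.mature + tc.autolyzed + tc.degraded
        np.testing.assert_allclose(total, 16.0, rtol=1e-7)
        # propeptide tracks total processing, not the surviving mature pool
        np.testing.assert_allclose(tc.propeptide, tc.mature + tc.degraded,
                                   rtol=1e-9)

    def test_closed_form_refuses_sinks(self):
        with pytest.raises(ValueError, match="sinks"):
            act.mm_depletion(mm_params(k_auto_per_s=1e-4), [0.0, 1.0],
                             method="closed_form")


class TestFitMMDepletion:
    def test_noise_free_exact_recovery(self):
        p = mm_params()
        t = np.linspace(0.0, 2400.0, 801)
        tc = act.mm_depletion(p, t, method="closed_form")
        res = act.fit_mm_depletion(t, tc.zymogen, p.activator_uM, p.z0_uM)
        assert res.km_identifiable
        assert res.km_uM == pytest.approx(4.5, rel=1e-6)
        assert res.kcat_per_s == pytest.approx(0.095, rel=1e-6)

    def test_noisy_recovery_within_stated_bounds(self):
        p = mm_params()
        t = np.linspace(0.0, 2400.0, 801)
        tc = act.mm_depletion(p, t, method="closed_form")
        kms, ratios = [], []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            z = tc.zymogen * (1 + rng.normal(0, 0.05, t.size))
            res = act.fit_mm_depletion(t, np.clip(z, 1e-6, None),
                                       p.activator_uM, p.z0_uM)
            kms.append(res.km_uM)
            ratios.append(res.kcat_over_km_uM_s)
        assert np.median(np.abs(np.array(kms) - 4.5) / 4.5) < 0.25
        truth = 0.095 / 4.5
        assert np.median(np.abs(np.array(ratios) - truth) / truth) < 0.10

    def test_purely_exponential_input_flags_km_unidentifiable(self):
        t = np.linspace(0.0, 2400.0, 400)
        z = 16.0 * np.exp(-0.002 * t)
        res = act.fit_mm_depletion(t, z, 0.16, 16.0)
        assert not res.km_identifiable
        assert np.isnan(res.km_uM)
        assert res.kcat_over_km_uM_s == pytest.approx(0.002 / 0.16, rel=1e-3)

    def test_flat_course_warns(self):
        t = np.linspace(0.0, 2400.0, 100)
        with pytest.warns(UserWarning, match="unidentifiable"):
            act.fit_mm_depletion(t, np.full(t.size, 16.0), 0.16, 16.0)


class TestSpeciesNetwork:
    def test_single_species_reduces_to_first_order_mm_limit(self):
        # one intact species processed first order == MM in the Km >> Z0 limit
        km, kcat = 5000.0, 0.095
        net = act.SpeciesNetwork(
            (act.NetworkSpecies("zym", 1.0, k_process=kcat / km),), z0_uM=16.0)
        t = np.linspace(0.0, 2400.0, 200)
        out = act.simulate_species_network(net, 0.16, t)
        mm = act.mm_depletion(mm_params(km_uM=km), t, method="closed_form")
        np.testing.assert_allclose(out["zym"], mm.zymogen, rtol=1e-2)
        np.testing.assert_allclose(out["mature"], mm.mature, atol=0.2)

    def test_unprocessable_mixture_stays_flat(self):
        net = act.SpeciesNetwork(
            (act.NetworkSpecies("f1", 0.5), act.NetworkSpecies("f2", 0.5)),
            z0_uM=16.0)
        t = np.linspace(0.0, 2400.0, 50)
        out = act.simulate_species_network(net, 0.16, t)
        np.testing.assert_allclose(out["f1"], 8.0)
        np.testing.assert_allclose(out["f2"], 8.0)
        np.testing.assert_allclose(out["mature"], 0.0)

    def test_total_protein_conserved(self):
        net = act.SpeciesNetwork(
            (act.NetworkSpecies("intact", 0.5, k_process=0.02, k_auto=1e-4),
             act.NetworkSpecies("trunc", 0.3, k_process=0.004,
                                k_truncate=0.002),
             act.NetworkSpecies("dead", 0.2)),
            z0_uM=16.0, k_deg_per_s=2e-5)
        t = np.linspace(0.0, 2400.0, 200)
        out = act.simulate_species_network(net, 0.16, t)
        total = (out["intact"] + out["trunc"] + out["dead"] + out["mature"]
                 + out["truncated_sink"] + out["autolysis_sink"]
                 + out["degraded"])
        np.testing.assert_allclose(total, 16.0, atol=1e-9)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            act.SpeciesNetwork((act.NetworkSpecies("a", 0.6),
                                act.NetworkSpecies("b", 0.6)))

    def test_coinciding_rates_handled(self):
        # defective eigenbasis (species rate == mature degradation rate)
        k = 0.01
        net = act.SpeciesNetwork(
            (act.NetworkSpecies("z", 1.0, k_process=k),),
            z0_uM=16.0, k_deg_per_s=k * 0.16)
        t = np.linspace(0.0, 2000.0, 60)
        out = act.simulate_species_network(net, 0.16, t)
        total = (out["z"] + out["mature"] + out["degraded"]
                 + out["truncated_sink"] + out["autolysis_sink"])
        np.testing.assert_allclose(total, 16.0, atol=1e-8)


class TestCrossModelConsistency:
    def test_kobs_slope_equals_specificity_in_sub_km_regime(self):
        # progress k_obs vs activator slope == kcat/Km when Z0 << Km
        km, kcat = 4.5, 0.095
        e1_list = np.array([0.0, 0.0005, 0.001, 0.0015, 0.002])  # uM
        kobs = kcat * e1_list / km     # first-order processing rates
        slope, intercept, _ = act.fit_kobs_linear(
            act.ActivatorSeries(e1_list, kobs))
        assert slope == pytest.approx(kcat / km, rel=0.10)
        assert intercept == pytest.approx(0.0, abs=1e-9)


class TestCalibration:
    def test_two_point_calibration_maps_linearly(self):
        slope, icpt = act.calibration_from_standards([0.0, 1.8], [0.0, 1800.0])
        assert act.fluorescence_to_concentration(900.0, slope, icpt) == \
            pytest.approx(0.9)

    def test_signal_equal_to_intercept_maps_to_zero(self):
        assert act.fluorescence_to_concentration(7.0, 1000.0, 7.0) == 0.0

    def test_round_trip_identity(self):
        slope, icpt = 973.2, 12.5
        conc = np.linspace(0.0, 1.8, 10)
        back = act.fluorescence_to_concentration(conc * slope + icpt,
                                                 slope, icpt)
        np.testing.assert_allclose(back, conc, atol=1e-12)

    def test_negatives_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = act.fluorescence_to_concentration(
                np.array([-5.0, 100.0]), 10.0, 0.0)
        assert out[0] == 0.0

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            act.fluorescence_to_concentration(1.0, 0.0, 0.0)


class TestProgressIO:
    def test_multi_curve_csv_round_trip(self, tmp_path):
        import pandas as pd
        t = np.arange(0.0, 100.0, 5.0)
        rows = []
        for cid, k in (("a", 0.01), ("b", 0.02)):
            p = act.progress_value(t, 0.0005, 0.005, k)
            for ti, pi in zip(t, p):
                rows.append((cid, ti, pi, 1.0))
        pd.DataFrame(rows, columns=["curve_id", "time_s", "product_uM",
                                    "activator_nM"]).to_csv(
            tmp_path / "p.csv", index=False)
        curves = act.read_progress_csv(tmp_path / "p.csv")
        assert len(curves) == 2
        assert curves[0].activator_nM == 1.0
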