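"""Closed-form mean-field relations, validity conditions, critical point."""

import numpy as np
import pytest

import lifcrit as lc


class TestValidity:
    def test_reference_configuration_is_valid(self, methods_p):
        rep = lc.check_validity(methods_p)
        assert rep.leak_refractory_value == pytest.approx(0.01)
        assert rep.drive_ratio_value == pytest.approx(50.0)
        assert rep.leak_drive_value == pytest.approx(0.5)
        assert rep.all_valid

    def test_zero_leak_satisfies_leak_conditions(self, methods_p):
        rep = lc.check_validity(methods_p.with_(alpha=0.0))
        assert rep.cond_leak_refractory  # 0 < 1/2
        assert rep.cond_leak_drive

    def test_strong_leak_violates_leak_drive(self, methods_p):
        rep = lc.check_validity(methods_p.with_(alpha=0.5))
        assert rep.leak_drive_value == pytest.approx(25.0)
        assert not rep.cond_leak_drive
        assert not rep.all_valid

    def test_undrivable_network_raises(self, methods_p):
        p = methods_p.with_(input_groups=((1000, 0.0),))
        with pytest.raises(ValueError, match="drivable"):
            lc.check_validity(p)


class TestWeightIsiRelations:
    def test_leaky_relation_at_reference_point(self, methods_p):
        # (0.01*5*64/(1-e^-0.08) - 6.4) / 700
        assert lc.w_of_delta_leaky(8.0, methods_p) == pytest.approx(
            0.05032, abs=5e-6
        )

    def test_leakfree_relation_at_reference_point(self, methods_p):
        assert lc.w_of_delta_leakfree(8.0, methods_p) == pytest.approx(0.048)

    def test_leakfree_zero_weight_isi(self, methods_p):
        # numerator root: <Delta> = tau*N*theta/(R*I)
        assert lc.w_of_delta_leakfree(50.0, methods_p) == pytest.approx(0.0, abs=1e-15)

    def test_divergence_at_refractory_pole(self, methods_p):
        # as <Delta> -> tau_ref+ the sustaining weight blows up
        assert lc.w_of_delta_leaky(1.0 + 1e-9, methods_p) > 1e6

    @pytest.mark.parametrize("op", [lc.w_of_delta_leaky, lc.w_of_delta_leakfree])
    def test_domain_error_at_or_below_tau_ref(self, methods_p, op):
        with pytest.raises(ValueError, match="tau_ref"):
            op(1.0, methods_p)

    def test_leaky_requires_positive_leak(self, methods_p):
        with pytest.raises(ValueError, match="alpha"):
            lc.w_of_delta_leaky(8.0, methods_p.with_(alpha=0.0))

    def test_leaky_converges_to_leakfree_as_leak_vanishes(self, methods_p):
        # mid-branch grid: near the zero-weight root (Delta = 50 ms) the
        # relative comparison is ill-conditioned by cancellation
        grid = np.linspace(1.5, 30.0, 60)
        free = lc.w_of_delta_leakfree(grid, methods_p)
        for alpha, tol in [(1e-3, 1e-1), (1e-6, 1e-4), (1e-8, 1e-6)]:
            leaky = lc.w_of_delta_leaky(grid, methods_p.with_(alpha=alpha))
            rel = np.max(np.abs(leaky - free) / np.abs(free))
            assert rel < tol


class TestInverseBranch:
    def test_zero_weight_gives_external_only_isi(self, methods_p):
        # a neuron needs ceil(theta/RI)=5 kicks arriving every tau*N=10 ms
        assert lc.delta_of_w_leakfree(0.0, methods_p) == pytest.approx(50.0)

    def test_critical_weight_maps_to_critical_isi(self, methods_p):
        assert lc.delta_of_w_leakfree(0.048, methods_p) == pytest.approx(8.0)

    def test_large_weight_limit_is_refractory_period(self, methods_p):
        d = lc.delta_of_w_leakfree(np.array([1e3, 1e4, 1e5]), methods_p)
        assert np.all(np.diff(np.abs(d - methods_p.tau_ref)) < 0)
        assert d[-1] == pytest.approx(methods_p.tau_ref, rel=1e-3)

    def test_inverse_identity_on_valid_branch(self, methods_p):
        grid = np.linspace(1.001, 50.0, 100)
        w = lc.w_of_delta_leakfree(grid, methods_p)
        back = lc.delta_of_w_leakfree(w, methods_p)
        assert np.max(np.abs(back - grid)) < 1e-9

    def test_strictly_decreasing_and_above_tau_ref(self, methods_p):
        w = np.linspace(0.0, 0.2, 500)
        d = lc.delta_of_w_leakfree(w, methods_p)
        assert np.all(np.diff(d) < 0)
        assert np.all(d > methods_p.tau_ref)


class TestCriticalPoint:
    def test_reference_values(self, methods_p):
        assert lc.critical_weight(methods_p) == pytest.approx(0.048)
        assert lc.critical_isi(methods_p) == pytest.approx(8.0)

    def test_zero_refractory_reduces_to_inverse_degree_scaling(self, methods_p):
        p = methods_p.with_(tau_ref=0.0)
        assert lc.critical_weight(p) == pytest.approx(
            p.threshold / (p.beta * p.n_neurons)
        )

    def test_homeostatic_configuration_value(self):
        p = lc.soqc_params(threshold=10.0, ri=2.0)
        assert lc.critical_weight(p) == pytest.approx(0.0996)

    def test_boundary_drive_ratio_gives_twice_tau_ref(self, methods_p):
        # theta*tau*N/(R*I*tau_ref) = 2  =>  Delta_crit = 2*tau_ref
        p = methods_p.with_(tau=2 * 1.0 / (1000 * 5.0))
        assert lc.critical_isi(p) == pytest.approx(2 * p.tau_ref)

    def test_critical_pair_is_on_leakfree_curve(self, methods_p):
        w = lc.w_of_delta_leakfree(lc.critical_isi(methods_p), methods_p)
        assert abs(w - lc.critical_weight(methods_p)) < 1e-12

    def test_critical_weight_independent_of_leak(self, methods_p):
        assert lc.critical_weight(methods_p) == lc.critical_weight(
            methods_p.with_(alpha=methods_p.alpha / 2)
        )

    def test_off_regime_warns_but_returns(self, methods_p):
        p = methods_p.with_(alpha=0.5)  # violates leak-drive condition
        with pytest.warns(UserWarning, match="validity"):
            lc.critical_weight(p)


class TestCurvatureStructure:
    def test_second_derivative_peaks_at_critical_weight(self, methods_p):
        wc = lc.critical_weight(methods_p)
        grid = np.linspace(0.5 * wc, 1.5 * wc, 2000)
        d = lc.delta_of_w_leakfree(grid, methods_p)
        d2 = np.gradient(np.gradient(d, grid), grid)
        peak = grid[np.argmax(d2)]
        assert abs(peak - wc) <= grid[1] - grid[0]

    def test_curvature_numerator_is_flat_in_weight(self, methods_p):
        # 2*g''*g - (g')^2 with g the discriminant polynomial is a constant
        p = methods_p
        n, ri, bn = p.n_neurons, p.effective_drive, p.beta * p.n_neurons
        c = 4 * p.beta * ri * p.tau_ref / p.tau

        def g(w):
            return (p.threshold - w * bn) ** 2 + c * w

        # central differences are exact for a quadratic, so h can be large
        # enough to keep roundoff negligible
        w = np.linspace(0.0, 0.2, 400)
        h = 1e-3
        g1 = (g(w + h) - g(w - h)) / (2 * h)
        g2 = (g(w + h) - 2 * g(w) + g(w - h)) / h**2
        num = 2 * g2 * g(w) - g1**2

        expected = (16 * p.beta**2 * n * ri * p.tau_ref / p.tau) * (
            p.threshold - ri * p.tau_ref / (p.tau * n)
        )
        assert np.max(np.abs(num - expected) / abs(expected)) < 1e-8


class TestMeanPotential:
    def test_initial_condition_is_reset(self, methods_p):
        assert lc.mean_potential(0.0, 8.0, 0.048, methods_p) == 0.0

    def test_reaches_threshold_at_mean_isi(self, methods_p):
        # the leaky relation is derived from <v(<Delta>)> = theta
        for d in (3.0, 8.0, 20.0, 40.0):
            w = lc.w_of_delta_leaky(d, methods_p)
            assert lc.mean_potential(d, d, w, methods_p) == pytest.approx(
                methods_p.threshold, abs=1e-9
            )

    def test_monotone_and_bounded_by_plateau(self, methods_p):
        t = np.linspace(0.0, 2000.0, 500)
        v = lc.mean_potential(t, 8.0, 0.048, methods_p)
        assert np.all(np.diff(v) > 0)
        rate = methods_p.effective_drive / (methods_p.tau * 1000) + 0.048 * 100 / 8 * (
            1 - 1 / 8
        )
        assert np.all(v < rate / methods_p.alpha + 1e-12)


class TestCurveContainer:
    def test_theory_curve_stays_above_refractory_pole(self, methods_p):
        curve = lc.mean_field_curve(methods_p, n_points=50)
        assert np.all(curve.mean_isi > methods_p.tau_ref)
        assert curve.source == "leaky_theory"

    def test_csv_round_trip(self, methods_p, tmp_path):
        import pandas as pd

        curve = lc.mean_field_curve(methods_p, n_points=20, source="leakfree_theory")
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["mean_isi_ms", "mean_weight_mV"]
        np.testing.assert_allclose(df["mean_weight_mV"], curve.mean_weight)
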