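"""Stress-strain construction, smoothing, modulus, yield, face-shift averaging."""

import numpy as np
import pytest

from polytherm import mechanics, synth
from polytherm.core.types import PolythermError, TimeSeries
from polytherm.mechanics import StressStrainCurve


def brute_force_smooth(strain, stress, h):
    """Independent O(n^2) rolling-window oracle with zero-stress pre-start
    padding (truncated early windows are topped up to full-window size)."""
    n = len(strain)
    order = np.argsort(strain, kind="stable")
    e, s = strain[order], stress[order]
    spacing = (e[-1] - e[0]) / (n - 1)
    n_full = int(round(2 * h / spacing)) + 1
    out_sorted = np.empty(n)
    for i in range(n):
        members = [s[j] for j in range(n) if e[i] - h <= e[j] <= e[i] + h]
        n_virtual = max(0, n_full - len(members)) if e[i] - h < e[0] else 0
        out_sorted[i] = sum(members) / (len(members) + n_virtual)
    out = np.empty(n)
    out[order] = out_sorted
    return out


def make_curve(strain, stress, h=0.025):
    t = np.arange(len(strain), dtype=float)
    pres = TimeSeries("P", t, -np.asarray(stress) * 1e4, unit="bar")
    eps = TimeSeries("strain", t, np.asarray(strain))
    return mechanics.stress_curve(pres, eps, half_window_strain=h)


class TestEngineeringStrain:
    def test_fifty_percent_elongation(self):
        ts = TimeSeries("L", [0.0, 1.0], [10.0, 15.0])
        np.testing.assert_allclose(mechanics.engineering_strain(ts).values, [0.0, 0.5])

    def test_constant_length_gives_zero_strain(self):
        ts = TimeSeries("L", np.arange(5.0), np.full(5, 8.0))
        assert np.all(mechanics.engineering_strain(ts).values == 0.0)

    def test_doubling_is_unit_strain(self):
        ts = TimeSeries("L", [0.0, 1.0], [7.0, 14.0])
        assert mechanics.engineering_strain(ts).values[-1] == pytest.approx(1.0)

    def test_zero_initial_length_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mechanics.engineering_strain(TimeSeries("L", [0.0, 1.0], [0.0, 1.0]))


class TestStressCurve:
    def test_constant_pressure_maps_to_constant_stress(self):
        strain = np.linspace(0, 1, 101)
        curve = make_curve(strain, np.full(101, 1.0))
        np.testing.assert_allclose(curve.stress, 1.0)
        # away from the padded pre-start region, smoothing is the identity
        interior = strain >= 0.025
        np.testing.assert_allclose(curve.smoothed[interior], 1.0)
        # inside it, the virtual zero-stress points pull the average down
        assert np.all(curve.smoothed[~interior] <= 1.0 + 1e-12)

    def test_smoothing_matches_brute_force_oracle(self, rng):
        strain = np.linspace(0, 1, 200)
        stress = rng.normal(0.2, 0.05, 200)
        curve = make_curve(strain, stress)
        np.testing.assert_allclose(curve.smoothed, brute_force_smooth(strain, stress, 0.025), atol=1e-12)

    def test_zero_mean_noise_averages_toward_zero(self, rng):
        strain = np.linspace(0, 1, 2000)
        stress = rng.normal(0.0, 1.0, 2000)
        curve = make_curve(strain, stress, h=0.2)
        assert np.abs(curve.smoothed[strain > 0.4]).max() < 0.3

    def test_linearity_in_pressure(self, rng):
        t = np.arange(50.0)
        eps = TimeSeries("strain", t, np.linspace(0, 0.5, 50))
        p1 = rng.normal(0, 1e3, 50)
        p2 = rng.normal(0, 1e3, 50)
        c1 = mechanics.stress_curve(TimeSeries("P", t, p1), eps)
        c2 = mechanics.stress_curve(TimeSeries("P", t, p2), eps)
        c12 = mechanics.stress_curve(TimeSeries("P", t, 2 * p1 - 3 * p2), eps)
        np.testing.assert_allclose(c12.stress, 2 * c1.stress - 3 * c2.stress, atol=1e-12)

    def test_misaligned_series_rejected(self):
        pres = TimeSeries("P", [0.0, 1.0], [0.0, 0.0])
        eps = TimeSeries("strain", [0.0, 2.0], [0.0, 0.1])
        with pytest.raises(PolythermError, match="aligned"):
            mechanics.stress_curve(pres, eps)


class TestYoungsModulus:
    def test_linear_curve_slope_recovered_exactly(self):
        strain = np.linspace(0, 0.1, 500)
        curve = make_curve(strain, 5.0 * strain)
        fit = mechanics.youngs_modulus(curve)
        assert fit.modulus_gpa == pytest.approx(5.0, rel=1e-10)
        assert fit.elastic

    def test_constant_stress_flagged_non_elastic(self):
        strain = np.linspace(0, 0.1, 100)
        curve = make_curve(strain, np.full(100, 0.2))
        fit = mechanics.youngs_modulus(curve)
        assert fit.modulus_gpa == 0.0 and not fit.elastic

    def test_synthetic_trace_recovery(self):
        pres, length = synth.gen_elastic_trace(8.0, 0.3, 0.00125, 1.0, 801, noise_sd_gpa=0.003, seed=2)
        curve = mechanics.stress_curve(pres, mechanics.engineering_strain(length))
        fit = mechanics.youngs_modulus(curve)
        assert fit.modulus_gpa == pytest.approx(8.0, rel=0.02)

    def test_empty_window_rejected(self):
        curve = make_curve(np.linspace(0, 0.001, 20), np.linspace(0, 0.01, 20))
        with pytest.raises(ValueError, match="window"):
            mechanics.youngs_modulus(curve)


class TestYieldStrength:
    def test_monotone_curve_yields_last_point_in_window(self):
        strain = np.linspace(0, 1, 101)
        curve = make_curve(strain, 0.5 * strain, h=1e-4)
        res = mechanics.yield_strength(curve)
        in_window = (strain >= 0.03) & (strain <= 0.97)
        assert res.yield_gpa == pytest.approx(curve.smoothed[in_window][-1])

    def test_plateau_value_recovered(self):
        strain = np.linspace(0, 1, 401)
        curve = make_curve(strain, np.minimum(8.0 * strain, 0.30), h=1e-4)
        res = mechanics.yield_strength(curve)
        assert res.yield_gpa == pytest.approx(0.30, abs=1e-9)

    def test_matches_exhaustive_max_oracle(self, rng):
        strain = np.linspace(0, 1, 300)
        curve = make_curve(strain, rng.normal(0.2, 0.05, 300))
        res = mechanics.yield_strength(curve)
        mask = (curve.strain >= 0.03) & (curve.strain <= 0.97)
        assert res.yield_gpa == max(curve.smoothed[mask])

    def test_invariant_to_points_outside_window(self, rng):
        strain = np.linspace(0, 1, 300)
        stress = rng.normal(0.2, 0.02, 300)
        base = mechanics.yield_strength(make_curve(strain, stress, h=1e-4))
        boosted = stress.copy()
        boosted[strain > 0.98] += 10.0  # outside [0.03, 0.97]
        res = mechanics.yield_strength(make_curve(strain, boosted, h=1e-4))
        assert res.yield_gpa == pytest.approx(base.yield_gpa)

    def test_tie_breaks_to_earliest_strain(self):
        strain = np.linspace(0, 1, 101)
        curve = StressStrainCurve(strain, np.zeros(101), np.minimum(strain * 2, 0.4))
        res = mechanics.yield_strength(curve)
        assert res.strain_at_yield == pytest.approx(0.2, abs=0.005)


class TestFaceShiftAverage:
    def test_identical_curves_are_fixed_point(self, rng):
        strain = np.linspace(0, 1, 50)
        c = make_curve(strain, rng.normal(0.2, 0.02, 50))
        avg = mechanics.face_shift_average([c] * 5)
        np.testing.assert_allclose(avg.smoothed, c.smoothed)

    def test_symmetric_perturbations_cancel(self, rng):
        strain = np.linspace(0, 1, 50)
        base = 0.3 * strain
        delta = rng.normal(0, 0.05, 50)
        up = StressStrainCurve(strain, base + delta, base + delta)
        down = StressStrainCurve(strain, base - delta, base - delta)
        avg = mechanics.face_shift_average([up, down])
        np.testing.assert_allclose(avg.smoothed, base, atol=1e-12)

    def test_matches_pointwise_mean_oracle(self, rng):
        strain = np.linspace(0, 1, 40)
        curves = [make_curve(strain, rng.normal(0.2, 0.05, 40)) for _ in range(5)]
        avg = mechanics.face_shift_average(curves)
        expected = np.mean([c.smoothed for c in curves], axis=0)
        np.testing.assert_allclose(avg.smoothed, expected, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            mechanics.face_shift_average([])
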