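"""Oxygen-flammability equations against independent high-precision oracles."""

import numpy as np
import pytest
import sympy as sp

from oxfire import oxygen as ox


def pi_oracle(o, m, clamp=True):
    """Term-by-term extended-precision evaluation of the ignition-probability
    polynomial (sympy rationals, 50-digit ln), independent of the package's
    float implementation."""
    o = sp.Rational(str(o))
    slope = (
        sp.Rational("308.02")
        - sp.Rational("27.406") * o
        + sp.Rational("0.634") * o**2
        - sp.Rational("0.0044") * o**3
    )
    intercept = (
        sp.Rational("-633.54")
        + sp.Rational("42.327") * o
        - sp.Rational("0.2194") * o**2
        - sp.Rational("0.0075") * o**3
    )
    val = sp.N(slope * sp.log(sp.Rational(str(m))) + intercept, 50)
    if clamp:
        val = min(max(val, sp.Integer(0)), sp.Integer(100))
    return float(val)


class TestProbabilityOfIgnition:
    def test_log_term_vanishes_at_unit_moisture(self):
        # ln(1) = 0 leaves only the oxygen-intercept part
        expected = -633.54 + 42.327 * 20.95 - 0.2194 * 20.95**2 - 0.0075 * 20.95**3
        assert ox.probability_of_ignition(20.95, 1.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "o,m", [(20.95, 20.0), (25.0, 5.0), (30.0, 15.0), (35.0, 20.0), (16.0, 2.0)]
    )
    def test_matches_extended_precision_oracle(self, o, m):
        assert ox.probability_of_ignition(o, m) == pytest.approx(
            pi_oracle(o, m), rel=1e-10
        )

    def test_higher_oxygen_ignites_wetter_fuel_more_readily(self):
        assert ox.probability_of_ignition(35.0, 20.0) > ox.probability_of_ignition(25.0, 20.0)
        assert pi_oracle(35.0, 20.0) > pi_oracle(25.0, 20.0)

    def test_monotone_in_oxygen_at_fixed_moisture(self):
        grid = np.arange(20.95, 35.0 + 1e-9, 0.1)
        for m in (5.0, 10.0, 20.0, 40.0):
            vals = ox.probability_of_ignition(grid, m)
            assert np.all(np.diff(vals) >= -1e-12)

    def test_monotone_decreasing_in_moisture(self):
        m_grid = np.linspace(1.0, 200.0, 400)
        for o in (20.95, 25.0, 30.0, 35.0):
            vals = ox.probability_of_ignition(o, m_grid)
            assert np.all(np.diff(vals) <= 1e-12)

    def test_clamped_to_probability_range(self):
        assert ox.probability_of_ignition(35.0, 1.0) == 100.0
        assert ox.probability_of_ignition(20.95, 200.0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ox.OxygenRangeError):
            ox.probability_of_ignition(15.0, 10.0)
        with pytest.raises(ox.OxygenRangeError):
            ox.probability_of_ignition(36.0, 10.0)
        with pytest.raises(ox.MoistureDomainError):
            ox.probability_of_ignition(25.0, 0.0)
        with pytest.raises(ox.MoistureDomainError):
            ox.probability_of_ignition(25.0, -3.0)


class TestIgnitionScaling:
    def test_self_normalisation_at_pal(self):
        for m in (1.0, 5.0, 15.0, 21.0, 50.0, 150.0):
            assert abs(ox.ignition_scaling(20.95, m) - 1.0) <= 1e-12

    def test_ratio_of_oracle_evaluations(self):
        got = ox.ignition_scaling(30.0, 15.0)
        want = pi_oracle(30.0, 15.0) / pi_oracle(20.95, 15.0)
        assert got == pytest.approx(want, rel=1e-10)

    def test_monotone_over_oxygen_sweep(self):
        grid = np.arange(20.95, 35.0 + 1e-9, 0.1)
        vals = ox.ignition_scaling(grid, 15.0)
        assert np.all(np.diff(vals) >= -1e-12)
        assert ox.ignition_scaling(35.0, 15.0) >= ox.ignition_scaling(21.0, 15.0)

    def test_wet_fuel_uses_capped_moisture(self):
        # beyond the PAL ignition range the factor freezes at its capped value
        cap = ox.moisture_cap()
        assert ox.ignition_scaling(30.0, cap + 50.0) == pytest.approx(
            ox.ignition_scaling(30.0, cap), rel=1e-12
        )
        # and stays finite and positive
        assert 0.0 < ox.ignition_scaling(35.0, 500.0) < 1e4

    def test_scaler_class_matches_function(self):
        scaler = ox.IgnitionScaler(28.0)
        m = np.array([3.0, 12.0, 40.0, 180.0])
        np.testing.assert_allclose(scaler(m), ox.ignition_scaling(28.0, m), rtol=1e-14)


class TestPerPftScalingAndAveraging:
    def test_scale_pft_ignition_cases(self):
        assert ox.scale_pft_ignition(0.2, True, 1.0, 5.0) == pytest.approx(0.2)
        assert ox.scale_pft_ignition(0.0, False, 3.0, 7.0) == 0.0
        assert ox.scale_pft_ignition(0.5, False, 2.0, 3.0) == pytest.approx(1.5)
        with pytest.raises(ValueError):
            ox.scale_pft_ignition(1.5, True, 1.0, 1.0)

    def test_weighted_average_identity_and_uniform(self):
        fpc = np.array([0.0, 0.4, 0.0])
        vals = np.array([1.0, 7.0, 9.0])
        assert ox.fpc_weighted_average(fpc, vals) == pytest.approx(7.0)
        assert ox.fpc_weighted_average(np.full(9, 0.1), np.arange(9.0)) == pytest.approx(
            np.arange(9.0).mean()
        )

    def test_weighted_average_against_loop_oracle(self):
        rng = np.random.default_rng(7)
        fpc = rng.random(9)
        vals = rng.normal(size=9) * 100
        want = sum(f * v for f, v in zip(fpc, vals)) / sum(fpc)
        assert ox.fpc_weighted_average(fpc, vals) == pytest.approx(want, rel=1e-12)

    def test_weighted_average_scale_invariant_and_bounded(self):
        rng = np.random.default_rng(11)
        fpc = rng.random(9)
        vals = rng.normal(size=9)
        a = ox.fpc_weighted_average(fpc, vals)
        b = ox.fpc_weighted_average(fpc * 37.5, vals)
        assert a == pytest.approx(b, rel=1e-12)
        assert vals.min() - 1e-12 <= a <= vals.max() + 1e-12

    def test_bare_ground_raises(self):
        with pytest.raises(ox.BareGroundError):
            ox.fpc_weighted_average(np.zeros(9), np.ones(9))


class TestOverallIgnitionEfficiency:
    def test_product_form(self):
        assert ox.overall_ignition_efficiency(0.0, 5.0, 0.9) == 0.0
        assert ox.overall_ignition_efficiency(1.0, 1.0, 1.0) == 1.0
        assert ox.overall_ignition_efficiency(0.3, 2.0, 0.5) == pytest.approx(0.3)

    def test_zero_iff_a_factor_is_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            f = rng.random(3) * 2
            if rng.random() < 0.5:
                f[rng.integers(3)] = 0.0
            out = ox.overall_ignition_efficiency(*f)
            assert (out == 0.0) == (f.prod() == 0.0)


class TestMoistureOfExtinction:
    def test_printed_values(self):
        assert ox.moisture_of_extinction(16.0) == pytest.approx(0.0, abs=1e-12)
        assert ox.moisture_of_extinction(20.95) == pytest.approx(39.6, rel=1e-12)
        assert ox.moisture_of_extinction(35.0) == pytest.approx(152.0, rel=1e-12)

    def test_exact_linearity(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(16, 35, 100)
        b = rng.uniform(16, 35, 100)
        lhs = ox.moisture_of_extinction(a) + ox.moisture_of_extinction(b)
        rhs = 2.0 * ox.moisture_of_extinction((a + b) / 2.0)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_below_fire_window_rejected(self):
        with pytest.raises(ox.OxygenRangeError):
            ox.moisture_of_extinction(15.9)

    def test_scaling_normalised_and_increasing(self):
        assert abs(ox.moisture_extinction_scaling(20.95) - 1.0) <= 1e-12
        assert ox.moisture_extinction_scaling(35.0) == pytest.approx(152.0 / 39.6, rel=1e-12)
        grid = np.arange(20.95, 35.0 + 1e-9, 0.1)
        assert np.all(np.diff(ox.moisture_extinction_scaling(grid)) > 0)


class TestHeatOfCombustion:
    def test_degenerate_and_asymptotic(self):
        assert ox.pft_heat_of_combustion(27.0, 0.0, 18500.0) == pytest.approx(18500.0)
        assert ox.pft_heat_of_combustion(1e9, -52375.0, 20000.0) == pytest.approx(
            20000.0, rel=1e-6
        )

    def test_configured_coefficients_at_pal(self):
        from oxfire import default_pfts

        for pft in default_pfts():
            want = pft.alpha / 20.95 + pft.beta
            assert ox.pft_heat_of_combustion(20.95, pft.alpha, pft.beta) == pytest.approx(
                want, rel=1e-12
            )
            # scheme recovers the per-form natural-fire heat at PAL
            assert want == pytest.approx(17500.0 if not pft.is_grass else 16500.0)

    def test_increases_with_oxygen_for_negative_alpha(self):
        grid = np.linspace(16.0, 35.0, 50)
        h = ox.pft_heat_of_combustion(grid, -52375.0, 20000.0)
        assert np.all(np.diff(h) > 0)

    def test_inconsistent_coefficients_rejected(self):
        with pytest.raises(ValueError):
            ox.pft_heat_of_combustion(20.0, -1e6, 100.0)
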