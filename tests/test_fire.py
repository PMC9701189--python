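"""Fire-behaviour engine: danger index, ignitions, spread, intensity,
burned area and mortality."""

import numpy as np
import pytest

from oxfire import fire as fb
from oxfire.config import FireConfig
from oxfire.fire import FuelBed


CFG = FireConfig()


def simple_bed(m_fine=10.0, m_woody=12.0, loads=(0.4, 0.2, 0.1, 0.3, 0.3)):
    return FuelBed(
        loads=np.array(loads, dtype=float).reshape(5, 1),
        moisture_fine=np.array([m_fine]),
        moisture_woody=np.array([m_woody]),
    )


class TestFireDanger:
    def test_reset_after_heavy_rain(self):
        idx = fb.nesterov_step(5000.0, 25.0, 10.0, 0.4, CFG)
        assert idx == 0.0
        assert fb.fdi_from_index(idx, CFG) == 0.0

    def test_monotone_over_rain_free_warm_spell(self):
        idx = 0.0
        seen = []
        for _ in range(30):
            idx = fb.nesterov_step(idx, 22.0, 0.0, 0.3, CFG)
            seen.append(float(idx))
        assert np.all(np.diff(seen) > 0)
        assert 0.0 < fb.fdi_from_index(seen[-1], CFG) < 1.0

    def test_dry_spell_matches_running_sum_oracle(self):
        rng = np.random.default_rng(2)
        temps = rng.uniform(10, 30, 30)
        rhs = rng.uniform(0.1, 0.6, 30)
        precips = np.zeros(30)
        # independent oracle: direct summation of the daily increments
        expected = sum(max(t, 0.0) * CFG.dewpoint_depression * (1.0 - r)
                       for t, r in zip(temps, rhs))
        got = fb.fire_danger_index(
            temps.reshape(-1, 1), precips.reshape(-1, 1), rhs.reshape(-1, 1), CFG
        )
        assert float(got[0]) == pytest.approx(
            1.0 - np.exp(-expected / CFG.nesterov_scale), rel=1e-12
        )

    def test_light_rain_does_not_reset(self):
        idx = fb.nesterov_step(1000.0, 20.0, CFG.nesterov_rain_reset - 0.1, 0.5, CFG)
        assert idx > 1000.0


class TestIgnitions:
    def test_zero_efficiency_gives_zero(self):
        assert fb.expected_ignitions(0.05, 0.0, 1e6, CFG) == 0.0

    def test_linear_in_lightning(self):
        one = fb.expected_ignitions(0.01, 0.2, 1e6, CFG)
        two = fb.expected_ignitions(0.02, 0.2, 1e6, CFG)
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_product_oracle(self):
        got = fb.expected_ignitions(0.03, 0.4, 2.5e6, CFG)
        assert got == pytest.approx(0.03 * CFG.ground_strike_fraction * 2.5e6 * 0.4)

    def test_negative_lightning_rejected(self):
        with pytest.raises(ValueError):
            fb.expected_ignitions(-0.1, 0.2, 1e6, CFG)


class TestRateOfSpread:
    def test_extinction_contract_at_every_swept_level(self):
        for ox in [20.95] + list(range(21, 36)):
            me_eff = fb.effective_extinction(float(ox), CFG.me_native, CFG)
            bed_me = float(np.max(me_eff))  # wetter than every class
            bed = simple_bed(m_fine=bed_me + 1.0, m_woody=bed_me + 1.0)
            assert float(fb.rate_of_spread(bed, 3.0, float(ox), CFG)[0]) == 0.0

    def test_monotone_in_oxygen(self):
        bed = simple_bed(m_fine=25.0, m_woody=28.0)
        ros = [float(fb.rate_of_spread(bed, 3.0, float(o), CFG)[0])
               for o in [20.95] + list(range(21, 36))]
        assert np.all(np.diff(ros) >= 0.0)
        assert ros[-1] > ros[0] > 0.0

    def test_oxygen_widens_the_burnable_window(self):
        # wetter than PAL extinction but drier than the 35 % level's
        bed = simple_bed(m_fine=60.0, m_woody=60.0)
        assert float(fb.rate_of_spread(bed, 3.0, 20.95, CFG)[0]) == 0.0
        assert float(fb.rate_of_spread(bed, 3.0, 35.0, CFG)[0]) > 0.0

    def test_denser_bed_does_not_spread_faster(self):
        light = simple_bed(loads=(0.1, 0.0, 0.0, 0.0, 0.6))   # grassy, airy
        dense = simple_bed(loads=(0.6, 0.3, 0.3, 0.0, 0.0))   # packed litter
        assert float(fb.rate_of_spread(dense, 3.0, 20.95, CFG)[0]) <= float(
            fb.rate_of_spread(light, 3.0, 20.95, CFG)[0]
        )

    def test_wind_speeds_spread(self):
        bed = simple_bed()
        calm = float(fb.rate_of_spread(bed, 0.0, 20.95, CFG)[0])
        windy = float(fb.rate_of_spread(bed, 8.0, 20.95, CFG)[0])
        assert windy > calm > 0.0

    def test_damping_polynomial_matches_direct_evaluation(self):
        r = np.linspace(0.0, 0.99, 40)
        want = 1.0 - 2.59 * r + 5.11 * r**2 - 3.52 * r**3
        np.testing.assert_allclose(fb.moisture_damping(r * 30.0, 30.0), want, rtol=1e-12)
        assert fb.moisture_damping(31.0, 30.0) == 0.0
        assert fb.moisture_damping(np.inf, 30.0) == 0.0

    def test_empty_bed_cannot_burn(self):
        bed = FuelBed(
            loads=np.zeros((5, 1)),
            moisture_fine=np.array([10.0]),
            moisture_woody=np.array([10.0]),
        )
        assert float(fb.rate_of_spread(bed, 5.0, 35.0, CFG)[0]) == 0.0


class TestIntensityAndArea:
    def test_byram_product(self):
        assert fb.fireline_intensity(18000.0, 1.0, 60.0) == pytest.approx(18000.0)
        assert fb.fireline_intensity(18000.0, 1.0, 0.0) == 0.0
        # linear in each argument
        base = fb.fireline_intensity(17000.0, 0.5, 6.0)
        assert fb.fireline_intensity(34000.0, 0.5, 6.0) == pytest.approx(2 * base)
        assert fb.fireline_intensity(17000.0, 1.0, 6.0) == pytest.approx(2 * base)
        assert fb.fireline_intensity(17000.0, 0.5, 12.0) == pytest.approx(2 * base)

    def test_burned_area_zero_without_spread(self):
        assert float(fb.burned_area(100.0, 0.0, 3.0, 1e6, 0.0, CFG)) == 0.0

    def test_burned_area_ellipse_oracle(self):
        n, ros, wind, area_km2 = 2.0, 5.0, 3.0, 1e4
        length_m = ros * CFG.fire_duration_min
        lb = 1.0 + 8.0 * (1.0 - np.exp(-CFG.length_breadth_wind * wind))
        per_fire_km2 = np.pi / 4.0 * length_m * (length_m / lb) / 1e6
        want = n * per_fire_km2 / area_km2
        assert float(fb.burned_area(n, ros, wind, area_km2, 0.0, CFG)) == pytest.approx(
            want, rel=1e-12
        )

    def test_burned_area_capped_at_remaining_fraction(self):
        got = float(fb.burned_area(1e9, 20.0, 3.0, 1e2, 0.7, CFG))
        assert got == pytest.approx(0.3)
        assert float(fb.burned_area(1e9, 20.0, 3.0, 1e2, 1.0, CFG)) == 0.0

    def test_consumption_damped_by_moisture(self):
        dry = simple_bed(m_fine=6.0, m_woody=6.0)
        wet = simple_bed(m_fine=25.0, m_woody=25.0)
        assert float(fb.fuel_consumed(dry, 20.95, CFG)[0]) > float(
            fb.fuel_consumed(wet, 20.95, CFG)[0]
        )
        # higher oxygen raises extinction moistures and hence consumption
        assert float(fb.fuel_consumed(wet, 35.0, CFG)[0]) > float(
            fb.fuel_consumed(wet, 20.95, CFG)[0]
        )


class TestMortality:
    def test_no_fire_no_kill(self):
        assert float(fb.fire_mortality(0.0, 0.7, CFG)) == 0.0

    def test_monotone_and_saturating(self):
        i = np.linspace(0, 2e4, 100)
        kill = fb.fire_mortality(i, 0.7, CFG)
        assert np.all(np.diff(kill) >= 0)
        assert np.all(kill <= 0.7 + 1e-12)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            fb.fire_mortality(-1.0, 0.5, CFG)


class TestFuelBed:
    def test_validation(self):
        with pytest.raises(ValueError):
            FuelBed(np.zeros((4, 1)), np.array([10.0]), np.array([10.0]))
        with pytest.raises(ValueError):
            FuelBed(-np.ones((5, 1)), np.array([10.0]), np.array([10.0]))
        with pytest.raises(ValueError):
            FuelBed(np.zeros((5, 1)), np.array([0.0]), np.array([10.0]))

    def test_class_moisture_pools(self):
        bed = simple_bed(m_fine=7.0, m_woody=33.0)
        cm = bed.class_moisture()[:, 0]
        np.testing.assert_allclose(cm, [7.0, 33.0, 33.0, 33.0, 7.0])

    def test_effective_extinction_scales_native_constants(self):
        me = fb.effective_extinction(35.0, CFG.me_native, CFG)
        np.testing.assert_allclose(me, np.array(CFG.me_native) * (152.0 / 39.6), rtol=1e-12)
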