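"""Closed-form physiology operations and the grain-number mechanism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import droughtwheat.physiology as phys
from droughtwheat.params import GrainSetParams, SoilProfile, default_soil
from droughtwheat.soilwater import infiltrate, soil_evaporation, soil_water_uptake


class TestThermalTime:
    @pytest.mark.parametrize("tmin,tmax,expected",
                             [(5, 15, 10.0), (-4, 2, 0.0), (10, 30, 20.0)])
    def test_mean_above_base(self, tmin, tmax, expected):
        assert phys.thermal_time_increment(tmin, tmax, 0.0) == expected

    def test_rejects_inverted_range(self):
        with pytest.raises(ValueError):
            phys.thermal_time_increment(10, 5, 0.0)


class TestFinalLeafNumber:
    def test_saturating_daylength_gives_base(self):
        assert phys.final_leaf_number(0.05, 15.0, fln_base=8.0,
                                      daylength_sat=15.0) == 8.0

    def test_short_day_shortfall(self):
        assert phys.final_leaf_number(0.70, 11.0, fln_base=8.0,
                                      daylength_sat=15.0) == pytest.approx(10.8)

    @given(pp=st.floats(0.05, 0.70), dl=st.floats(0.0, 24.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_pp(self, pp, dl):
        low = phys.final_leaf_number(0.05, dl)
        assert phys.final_leaf_number(pp, dl) >= low - 1e-12


class TestInterception:
    def test_examples(self):
        assert phys.intercepted_fraction(0.0, 0.45) == 0.0
        assert phys.intercepted_fraction(3.0, 0.45) == pytest.approx(
            1 - math.exp(-1.35))
        assert phys.intercepted_fraction(40.0, 0.45) == pytest.approx(1.0, abs=1e-6)

    def test_strictly_increasing(self):
        lais = np.linspace(0, 10, 30)
        fs = [phys.intercepted_fraction(x) for x in lais]
        assert all(b > a for a, b in zip(fs, fs[1:]))

    def test_rejects_negative_lai(self):
        with pytest.raises(ValueError):
            phys.intercepted_fraction(-0.1)


class TestRueCO2:
    def test_identity_at_reference(self):
        assert phys.rue_co2_multiplier(350, 350) == 1.0

    def test_doubling_gives_30_percent(self):
        assert phys.rue_co2_multiplier(700, 350) == pytest.approx(1.30)

    def test_scenario_concentration(self):
        assert phys.rue_co2_multiplier(541, 350) == pytest.approx(
            1 + 0.3 * (541 / 350 - 1))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            phys.rue_co2_multiplier(0, 350)


class TestWaterStressResponse:
    @pytest.mark.parametrize("sf,wsa,expected", [
        (1.0, 2.1, 1.0),          # unstressed: multiplier exactly 1
        (0.5, 1.0, 0.5),          # proportional response
        (0.5, 0.1, 0.5 ** 0.1),   # weak response = tolerance (~0.933)
    ])
    def test_multiplier(self, sf, wsa, expected):
        assert phys.water_stress_multiplier(sf, wsa) == pytest.approx(expected)

    def test_assimilation_zero_without_radiation_or_water(self):
        assert phys.assimilation(0.0, 0.5, 3.0, 1.0, 0.5) == 0.0
        assert phys.assimilation(20.0, 0.5, 3.0, 0.0, 0.5) == 0.0


class TestPriestleyTaylor:
    def test_zero_radiation_or_bare_soil(self, consts):
        assert phys.priestley_taylor_et(0.0, 20.0) == 0.0
        assert phys.potential_transpiration(20.0, 20.0, 0.0, consts) == 0.0

    def test_matches_independent_implementation(self):
        # oracle: textbook Priestley-Taylor with the same Rn approximation
        t, srad, rn_f = 20.0, 20.0, 0.55
        es = 0.6108 * math.exp(17.27 * t / (t + 237.3))
        slope = 4098 * es / (t + 237.3) ** 2
        expected = 1.26 * slope / (slope + 0.066) * (rn_f * srad) / 2.45
        assert phys.priestley_taylor_et(srad, t, 1.26, rn_f) == pytest.approx(expected)


class TestStressFactor:
    @pytest.mark.parametrize("ta,tp,expected",
                             [(2.0, 2.0, 1.0), (0.0, 3.0, 0.0), (1.5, 3.0, 0.5),
                              (0.0, 0.0, 1.0)])
    def test_ratio(self, ta, tp, expected):
        assert phys.stress_factor(ta, tp) == expected

    def test_rejects_supply_above_demand(self):
        with pytest.raises(ValueError):
            phys.stress_factor(2.0, 1.0)


class TestDSF:
    def test_ratio_of_sums(self):
        assert phys.compute_dsf([1.0] * 15, [1.0] * 15) == 1.0
        assert phys.compute_dsf([0.0] * 15, [1.0] * 15) == 0.0
        assert phys.compute_dsf([1.0] * 15, [2.0] * 15) == 0.5

    def test_no_demand_means_no_stress(self):
        assert phys.compute_dsf([0.0] * 15, [0.0] * 15) == 1.0

    def test_rejects_mismatched_windows(self):
        with pytest.raises(ValueError):
            phys.compute_dsf([1.0] * 14, [1.0] * 15)


class TestGrainReduction:
    def test_printed_parameterization(self):
        p = GrainSetParams()
        assert phys.grain_reduction_factor(0.25, p) == 0.2  # saturated branch
        assert phys.grain_reduction_factor(0.95, p) == 1.0  # above threshold
        # linear branch, hand evaluation: 0.2 + (0.8/0.6)*(0.6-0.3) = 0.6
        assert phys.grain_reduction_factor(0.6, p) == pytest.approx(0.6)

    def test_continuity_at_both_breakpoints(self):
        p = GrainSetParams()
        eps = 1e-9
        assert phys.grain_reduction_factor(p.dsgns + eps, p) == pytest.approx(
            p.dsgnr_max, abs=1e-6)
        assert phys.grain_reduction_factor(p.dsgnt - eps, p) == pytest.approx(
            1.0, abs=1e-6)

    def test_tolerant_flag_disables_reduction(self):
        p = GrainSetParams(tolerant=True)
        for dsf in (0.0, 0.25, 0.6, 1.0):
            assert phys.grain_reduction_factor(dsf, p) == 1.0

    @given(dsf=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_nondecreasing(self, dsf):
        p = GrainSetParams()
        r = phys.grain_reduction_factor(dsf, p)
        assert p.dsgnr_max <= r <= 1.0
        assert phys.grain_reduction_factor(min(1.0, dsf + 0.01), p) >= r - 1e-12

    def test_invalid_parameterization_rejected(self):
        with pytest.raises(ValueError):
            GrainSetParams(dsgns=0.9, dsgnt=0.3)
        with pytest.raises(ValueError):
            GrainSetParams(dsgnr_max=0.0)


class TestSinkCapacity:
    def test_examples(self):
        p = GrainSetParams()
        assert phys.sink_capacity(0.0, 1.0, p) == (0.0, 0.0)
        gn, ypot = phys.sink_capacity(500.0, 1.0, p)
        assert gn == pytest.approx(50_000.0) and ypot == pytest.approx(2_500.0)
        gn, ypot = phys.sink_capacity(500.0, 0.2, p)
        assert gn == pytest.approx(10_000.0) and ypot == pytest.approx(500.0)


class TestSoilWater:
    def test_default_profile_totals(self, soil):
        assert soil.total_awc == pytest.approx(177.0)
        assert np.all(np.diff(soil.lambda_profile) <= 1e-12)

    def test_zero_demand_and_dry_profile(self, soil):
        water = soil.awc_per_layer.copy()
        ta, after = soil_water_uptake(water, 0.0, 1.5, 3.0, soil)
        assert ta == 0.0 and np.array_equal(after, water)
        ta, _ = soil_water_uptake(np.zeros(soil.n_layers), 5.0, 1.5, 3.0, soil)
        assert ta == 0.0

    def test_uptake_conserves_water(self, soil):
        water = soil.awc_per_layer.copy()
        ta, after = soil_water_uptake(water, 1.0, 1.5, 7.0, soil)
        assert ta == pytest.approx(1.0)
        assert water.sum() - after.sum() == pytest.approx(ta, abs=1e-12)

    def test_layers_below_roots_untouched(self, soil):
        water = soil.awc_per_layer.copy()
        _, after = soil_water_uptake(water, 50.0, 0.10, 7.0, soil)
        assert np.array_equal(after[2:], water[2:])
        assert np.any(after[:2] < water[:2])

    def test_infiltration_overflow_is_drainage(self, soil):
        water = soil.awc_per_layer.copy()
        water[:5] = 0.0
        after, drained = infiltrate(water, 100.0, soil)
        assert after.sum() - water.sum() + drained == pytest.approx(100.0)
        assert np.all(after <= soil.awc_per_layer + 1e-12)

    def test_evaporation_throttled_by_dryness(self, soil):
        full = soil.awc_per_layer.copy()
        _, e_full = soil_evaporation(full, 3.0, soil)
        half = full.copy()
        half[:2] *= 0.5
        _, e_half = soil_evaporation(half, 3.0, soil)
        assert e_full == pytest.approx(3.0)
        assert e_half == pytest.approx(1.5)

    def test_lambda_must_not_increase_with_depth(self):
        with pytest.raises(ValueError):
            SoilProfile(0.05, np.full(3, 5.0), np.array([0.5, 0.9, 1.0]), 0.15)
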