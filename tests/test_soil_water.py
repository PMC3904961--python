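"""Runoff, drainage, evaporation stages, root zone and daily closure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aquawheat as aw
from aquawheat.params import CropParams, ParameterError
from aquawheat.soil_water import (SoilError, SoilProfile, WaterState,
                                  curve_number_runoff, drain_profile,
                                  root_deepening, soil_evaporation,
                                  step_water_balance, update_root_zone)


@pytest.fixture
def profile():
    return SoilProfile.xiaotangshan()


class TestCurveNumberRunoff:
    def test_no_rain_no_runoff(self):
        assert curve_number_runoff(0.0, 75.0) == 0.0

    def test_hand_evaluated_scs_value(self):
        """CN=75, 50 mm: S=84.667, Ia=16.933, Q=(50-Ia)^2/(50-Ia+S)."""
        s = 25400.0 / 75.0 - 254.0
        ia = 0.2 * s
        expected = (50.0 - ia) ** 2 / (50.0 - ia + s)
        assert curve_number_runoff(50.0, 75.0) == pytest.approx(expected)
        assert expected == pytest.approx(9.29, abs=0.01)

    def test_below_initial_abstraction_is_zero(self):
        s = 25400.0 / 75.0 - 254.0
        assert curve_number_runoff(0.2 * s, 75.0) == 0.0

    def test_cn_100_limit_all_runoff(self):
        assert curve_number_runoff(30.0, 100.0) == pytest.approx(30.0)

    @pytest.mark.parametrize("cn", [0.0, -5.0, 101.0])
    def test_cn_out_of_range(self, cn):
        with pytest.raises(ParameterError):
            curve_number_runoff(10.0, cn)

    @settings(derandomize=True, max_examples=50)
    @given(r1=st.floats(0.0, 200.0), r2=st.floats(0.0, 200.0))
    def test_monotone_in_rain(self, r1, r2):
        lo, hi = sorted([r1, r2])
        assert curve_number_runoff(hi, 75.0) >= curve_number_runoff(lo, 75.0)

    @settings(derandomize=True, max_examples=50)
    @given(rain=st.floats(0.0, 500.0))
    def test_bounded_by_rain(self, rain):
        q = curve_number_runoff(rain, 75.0)
        assert 0.0 <= q <= rain


class TestDrainage:
    def test_at_field_capacity_no_drainage(self, profile):
        state = WaterState.at_field_capacity(profile)
        assert drain_profile(state, profile) == 0.0
        assert np.allclose(state.theta, profile.fc)

    def test_saturated_top_returns_to_fc(self, profile):
        state = WaterState.at_field_capacity(profile)
        state.theta[0] = profile.sat[0]
        before = state.storage_mm(profile)
        perc = drain_profile(state, profile)
        assert state.theta[0] == pytest.approx(profile.fc[0])
        # mass conserved: excess went below or out
        assert state.storage_mm(profile) + perc == pytest.approx(before, abs=1e-9)

    def test_no_layer_exceeds_saturation(self, profile):
        state = WaterState.at_field_capacity(profile)
        for _ in range(10):
            from aquawheat.soil_water import infiltrate
            infiltrate(state, profile, 80.0)
            drain_profile(state, profile)
            assert np.all(state.theta <= profile.sat + 1e-9)


class TestSoilEvaporation:
    def test_full_cover_no_evaporation(self, profile):
        state = WaterState.at_field_capacity(profile)
        assert soil_evaporation(state, profile, cc=1.0, eto=5.0) == 0.0

    def test_stage_one_ceiling(self, profile):
        """Bare wet soil evaporates at the 1.1*ETo energy limit."""
        state = WaterState.at_field_capacity(profile)
        assert soil_evaporation(state, profile, cc=0.0, eto=4.0) == \
            pytest.approx(1.1 * 4.0)

    def test_partial_cover_scales_ceiling(self, profile):
        state = WaterState.at_field_capacity(profile)
        e = soil_evaporation(state, profile, cc=0.6, eto=4.0)
        assert e <= (1 - 0.6) * 1.1 * 4.0 + 1e-12

    def test_dry_down_declines_monotonically(self, profile):
        state = WaterState.at_field_capacity(profile)
        es = [soil_evaporation(state, profile, cc=0.0, eto=5.0)
              for _ in range(15)]
        assert all(b <= a + 1e-12 for a, b in zip(es, es[1:]))
        assert es[-1] < es[0]  # falling-rate stage reached

    def test_floor_at_air_dry(self, profile):
        state = WaterState.at_field_capacity(profile)
        for _ in range(200):
            soil_evaporation(state, profile, cc=0.0, eto=8.0)
        assert state.theta[0] >= 0.5 * profile.wp[0] - 1e-9


class TestRootZone:
    def test_at_fc_zero_depletion(self, profile):
        state = WaterState.at_field_capacity(profile)
        taw, dr = update_root_zone(state, 1.0, profile)
        assert dr == 0.0 and taw > 0.0

    def test_at_wp_depletion_equals_taw(self, profile):
        state = WaterState(theta=profile.wp.astype(float).copy())
        taw, dr = update_root_zone(state, 1.0, profile)
        assert dr == pytest.approx(taw)

    def test_measured_layers_taw_at_30cm(self, profile):
        """TAW over the characterised 0.3 m: 18.5 + 18.6 + 21.6 = 58.7 mm."""
        state = WaterState.at_field_capacity(profile)
        taw, _ = update_root_zone(state, 0.3, profile)
        assert taw == pytest.approx(58.7)

    def test_partial_compartment_pro_rata(self, profile):
        state = WaterState.at_field_capacity(profile)
        taw_25, _ = update_root_zone(state, 0.25, profile)
        assert taw_25 == pytest.approx(18.5 + 18.6 + 0.5 * 21.6)

    def test_root_depth_beyond_profile_is_error(self, profile):
        state = WaterState.at_field_capacity(profile)
        with pytest.raises(SoilError):
            update_root_zone(state, 5.0, profile)


class TestRootDeepening:
    def test_emergence_depth(self):
        crop = CropParams()
        assert root_deepening(0, crop) == pytest.approx(0.3)
        assert root_deepening(crop.emergence_day, crop) == pytest.approx(0.3)

    def test_max_depth_reached_and_held(self):
        crop = CropParams()
        assert root_deepening(crop.max_root_day, crop) == pytest.approx(1.2)
        assert root_deepening(300, crop) == pytest.approx(1.2)

    def test_midpoint_follows_power_law(self):
        crop = CropParams()
        t0, t1 = crop.emergence_day, crop.max_root_day
        mid = (t0 + t1) / 2
        expected = 0.3 + (1.2 - 0.3) * 0.5 ** (1 / 1.5)
        assert root_deepening(mid, crop) == pytest.approx(expected)

    def test_monotone_non_decreasing(self):
        crop = CropParams()
        depths = [root_deepening(d, crop) for d in range(0, 260, 5)]
        assert all(b >= a for a, b in zip(depths, depths[1:]))


class TestStepClosure:
    def test_quiet_day_changes_nothing(self, profile):
        state = WaterState.at_field_capacity(profile)
        before = state.theta.copy()
        f = step_water_balance(state, profile, rain=0.0, irrigation=0.0,
                               cc=0.5, eto=0.0, transp_demand=0.0, root_depth=1.0)
        assert f.runoff == f.percolation == f.evaporation == f.transpiration == 0.0
        assert np.allclose(state.theta, before)

    def test_irrigation_event_closes_budget(self, profile):
        """68 mm onto an FC profile: budget closes daily over a 5-day window."""
        state = WaterState.at_field_capacity(profile)
        perc_total = 0.0
        for day in range(5):
            irr = 68.0 if day == 0 else 0.0
            f = step_water_balance(state, profile, rain=0.0, irrigation=irr,
                                   cc=0.3, eto=3.0, transp_demand=1.0,
                                   root_depth=0.6)
            balance = irr - (f.runoff + f.percolation + f.evaporation
                             + f.transpiration + f.delta_storage)
            assert abs(balance) < 1e-6
            perc_total += f.percolation
        assert perc_total > 40.0  # most of the slug drains past an FC profile

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 60), st.floats(0, 8)),
                    min_size=5, max_size=30))
    def test_random_forcing_closes_and_stays_physical(self, forcing):
        """Any rain/ETo sequence closes each day and respects physical bounds."""
        profile = SoilProfile.xiaotangshan()
        state = WaterState.at_fraction(profile, 0.7)
        for rain, eto in forcing:
            before = state.storage_mm(profile)
            f = step_water_balance(state, profile, rain=rain, irrigation=0.0,
                                   cc=0.4, eto=eto, transp_demand=0.5 * eto,
                                   root_depth=1.0)
            closure = rain - (f.runoff + f.percolation + f.evaporation
                              + f.transpiration + f.delta_storage)
            assert abs(closure) < 1e-6
            assert np.all(state.theta <= profile.sat + 1e-9)
            _, dr = update_root_zone(state, 1.0, profile)
            assert dr >= 0.0

    def test_negative_inputs_rejected(self, profile):
        state = WaterState.at_field_capacity(profile)
        with pytest.raises(SoilError):
            step_water_balance(state, profile, rain=-1.0, irrigation=0.0,
                               cc=0.5, eto=1.0, transp_demand=0.0, root_depth=1.0)


class TestSoilConfig:
    def test_layer_ordering_enforced(self):
        with pytest.raises(SoilError):
            aw.SoilLayer(0.1, 30.0, 35.0, 8.0, 100.0)

    def test_xiaotangshan_profile_shape(self, profile):
        assert profile.depth == pytest.approx(1.3)
        assert profile.curve_number == 75.0
        assert profile.groundwater_depth == 3.5
        # extension reuses the deepest measured layer
        assert profile.fc[-1] == profile.fc[2]
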