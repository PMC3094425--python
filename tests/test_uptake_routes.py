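"""The three route-specific uptake equations and the indoor box model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddtexpo.concentration_db import UniformDist
from ddtexpo.uptake_routes import (
    DermalSetting,
    FoodGroupIntake,
    InhalationSetting,
    dermal_uptake_bounds,
    dietary_uptake,
    indoor_air_mass_balance,
    inhalation_uptake,
)


class TestDietaryUptake:
    def test_direct_multiplication(self):
        per, total = dietary_uptake(
            [FoodGroupIntake("dairy", 100.0, 0.04)], {"dairy": 50.0}, e_diet=0.9
        )
        assert per["dairy"] == pytest.approx(180.0)
        assert total == pytest.approx(180.0)

    def test_zero_concentration_gives_zero_uptake(self):
        per, _ = dietary_uptake(
            [FoodGroupIntake("meat", 200.0, 0.2)], {"meat": 0.0}
        )
        assert per["meat"] == 0.0

    def test_total_is_additive_over_groups(self):
        intakes = [FoodGroupIntake(g, 100.0, 0.1) for g in ("a", "b", "c")]
        conc = {g: 60.0 / (100.0 * 0.1 * 0.9) for g in ("a", "b", "c")}
        _, total = dietary_uptake(intakes, conc)
        assert total == pytest.approx(180.0)

    def test_missing_concentration_names_group(self):
        with pytest.raises(KeyError, match="grains"):
            dietary_uptake([FoodGroupIntake("grains", 10.0, 0.02)], {})

    def test_vectorized_over_mc_samples(self):
        c = np.array([10.0, 20.0, 30.0])
        per, total = dietary_uptake(
            [FoodGroupIntake("fish_marine", 50.0, 0.1)], {"fish_marine": c}, e_diet=1.0
        )
        assert np.allclose(total, 5.0 * c)


class TestInhalationUptake:
    def test_zero_everywhere(self):
        s = InhalationSetting(v_inh=15.0, indoor_equals_outdoor=False)
        assert inhalation_uptake(s, 0.0, 0.0, 0.0) == 0.0

    def test_indoor_gas_phase(self):
        s = InhalationSetting(v_inh=15.0, indoor_fraction=1 / 3,
                              indoor_equals_outdoor=False)
        assert inhalation_uptake(s, 0.0, 1000.0, 0.0) == pytest.approx(5000.0)

    def test_indoor_particle_phase_uses_reduced_efficiency(self):
        s = InhalationSetting(v_inh=15.0, indoor_fraction=1 / 3,
                              indoor_equals_outdoor=False)
        assert inhalation_uptake(s, 0.0, 0.0, 1000.0) == pytest.approx(2200.0)

    def test_indoor_equals_outdoor_collapses_to_outdoor_gas(self):
        s = InhalationSetting(v_inh=15.0, indoor_fraction=0.5,
                              indoor_equals_outdoor=True)
        # indoor arguments must be ignored entirely
        assert inhalation_uptake(s, 2.0, 999.0, 999.0) == pytest.approx(30.0)

    def test_zero_indoor_fraction_ignores_indoor_air(self):
        s = InhalationSetting(v_inh=10.0, indoor_fraction=0.0,
                              indoor_equals_outdoor=False)
        assert inhalation_uptake(s, 5.0, 777.0, 777.0) == pytest.approx(50.0)

    def test_rejects_negative_concentration(self):
        s = InhalationSetting(v_inh=15.0)
        with pytest.raises(ValueError):
            inhalation_uptake(s, -1.0)

    def test_generic_efficiency_switch(self):
        s = InhalationSetting(v_inh=10.0, indoor_equals_outdoor=True)
        g = s.with_generic_efficiency()
        assert g.e_gas == g.e_particle == 0.75
        assert inhalation_uptake(g, 1.0) == pytest.approx(7.5)


class TestDermalUptake:
    def test_zero_concentration_bounds(self):
        d = dermal_uptake_bounds(DermalSetting(c_sd_min=0.0, c_sd_max=0.0))
        assert d == UniformDist(0.0, 0.0)

    def test_point_mass_direct_multiplication(self):
        s = DermalSetting(sda=1.0, ae_min=1000.0, ae_max=1000.0,
                          c_sd_min=10.0, c_sd_max=10.0, ur_derm=0.01)
        d = dermal_uptake_bounds(s)
        assert d.lower == pytest.approx(100.0)
        assert d.upper == pytest.approx(100.0)

    def test_default_skin_area_and_adherence(self):
        s = DermalSetting()
        assert (s.ae_min, s.ae_max) == (1120.0, 9550.0)
        assert s.sda == 1.0

    def test_bounds_ordered(self):
        d = dermal_uptake_bounds(DermalSetting(c_sd_min=0.1, c_sd_max=10.0))
        assert d.lower <= d.upper

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            DermalSetting(c_sd_min=5.0, c_sd_max=1.0)


class TestIndoorAirMassBalance:
    def test_no_emission_no_concentration(self):
        assert indoor_air_mass_balance(0.0, 50.0, 30.0, 24.0) == 0.0

    def test_direct_evaluation(self):
        c = indoor_air_mass_balance(48_000.0, 50.0, 30.0, 24.0)
        assert c == pytest.approx(3333.3, rel=1e-3)

    def test_plausible_irs_parameterization_in_microgram_range(self):
        # tens of µg/m²/day evaporating off treated walls (a small daily
        # fraction of the ~2 g/m² applied), moderately ventilated room
        c = indoor_air_mass_balance(
            emission_flux=60_000.0, treated_area=40.0, room_volume=30.0,
            air_exchange_rate=12.0,
        )
        assert 1_000.0 <= c <= 10_000.0  # i.e. 1-10 µg/m³

    def test_rejects_zero_air_exchange(self):
        with pytest.raises(ValueError, match="steady state"):
            indoor_air_mass_balance(1.0, 50.0, 30.0, 0.0)


@settings(max_examples=50, derandomize=True)
@given(lam=st.floats(0.001, 1000.0), c=st.floats(0.0, 1e6))
def test_uptake_operators_linear_in_concentration(lam, c):
    _, diet = dietary_uptake([FoodGroupIntake("g", 10.0, 0.1)], {"g": c}, e_diet=0.9)
    _, diet_s = dietary_uptake([FoodGroupIntake("g", 10.0, 0.1)], {"g": lam * c}, e_diet=0.9)
    assert diet_s == pytest.approx(lam * diet, rel=1e-9, abs=1e-9)

    s = InhalationSetting(v_inh=15.0, indoor_fraction=1 / 3, indoor_equals_outdoor=False)
    u = inhalation_uptake(s, c, c, c)
    assert inhalation_uptake(s, lam * c, lam * c, lam * c) == pytest.approx(
        lam * u, rel=1e-9, abs=1e-9
    )
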