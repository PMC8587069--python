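"""Clothing microclimate physics: correlations, insulation arithmetic,
evaporation and the clothing-layer balances.

Numeric expectations marked as oracles were hand-evaluated from the
restored serial-resistance / correlation forms before implementation and
frozen here.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermoclo as tc
from thermoclo.clothing import (AirProperties, Fabric, Garment, KELVIN,
                                clo_convert, clo_invert, clothing_area_factor,
                                clothing_derivatives, diffusion_loss,
                                evaporative_coefficient, fabric_flux,
                                gap_coefficient, intrinsic_insulation,
                                max_evaporation, nusselt_enclosure,
                                operative_temperature,
                                outer_convective_coefficient,
                                outer_to_env_flux, radiant_exchange_factor,
                                rayleigh_number, saturation_vapor_pressure,
                                sensible_exchange_bare, skin_evaporation,
                                skin_to_inner_flux,
                                total_heat_transfer_coefficient,
                                total_insulation)

AIR = AirProperties.standard()
SIGMA = AIR.sigma


class TestSaturationPressure:
    def test_boiling_point_within_one_percent(self):
        assert saturation_vapor_pressure(100.0) == pytest.approx(101.325, rel=0.01)

    def test_steam_table_at_35C(self):
        # published steam-table value 5.628 kPa
        assert saturation_vapor_pressure(35.0) == pytest.approx(5.628, rel=2e-3)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(min_value=-20.0, max_value=109.0))
    def test_monotone_increasing(self, T):
        assert saturation_vapor_pressure(T + 1.0) > saturation_vapor_pressure(T)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            saturation_vapor_pressure(-30.0)


class TestInsulationArithmetic:
    def test_area_factor_examples(self):
        assert clothing_area_factor(0.140, 0.140) == 1.0
        assert clothing_area_factor(0.1886, 0.175) == pytest.approx(
            1.0777142857142856, rel=1e-12)
        with pytest.raises(ValueError):
            clothing_area_factor(0.0, 0.1)

    def test_total_insulation(self):
        assert total_insulation(34.0, 24.0, 100.0) == pytest.approx(0.1)
        assert total_insulation(33.0, 33.0, 50.0) == 0.0
        assert total_insulation(34.0, 24.0, 200.0) == pytest.approx(0.05)
        with pytest.raises(ValueError):
            total_insulation(34.0, 24.0, 0.0)

    def test_intrinsic_insulation(self):
        assert intrinsic_insulation(0.2, 0.1, 1.0) == pytest.approx(0.1)
        assert intrinsic_insulation(0.109, 0.109, 1.0) == 0.0   # nude manikin
        assert intrinsic_insulation(0.186, 0.109, 1.0777) == pytest.approx(
            0.08485868052333674, rel=1e-9)

    def test_clo_examples(self):
        assert clo_convert(0.155) == pytest.approx(1.0)
        assert clo_convert(0.0) == 0.0
        assert clo_invert(0.155) == pytest.approx(0.024025, rel=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.0, max_value=5.0))
    def test_clo_round_trip(self, I):
        assert clo_convert(clo_invert(I)) == pytest.approx(I, rel=1e-12, abs=1e-15)


class TestEvaporation:
    def test_coefficient_oracle(self):
        assert evaporative_coefficient(1.0, 0.34, 3.0, 1.08, 16.5) \
            == pytest.approx(21.582047019710284, rel=1e-9)

    def test_bare_skin_limit(self):
        # I_cl -> 0 recovers the Lewis relation LR h_c f_cl
        assert evaporative_coefficient(0.0, 0.34, 4.0, 1.0, 16.5) \
            == pytest.approx(16.5 * 4.0, rel=1e-12)

    def test_impermeable_limit(self):
        assert evaporative_coefficient(1.0, 1e-12, 3.0, 1.08, 16.5) \
            == pytest.approx(0.0, abs=1e-9)

    def test_max_evaporation(self):
        p = saturation_vapor_pressure(33.6)
        assert max_evaporation(10.0, 33.6, p, 0.175) == 0.0   # saturated air
        assert max_evaporation(10.0, 33.6, 1.0, 0.0) == 0.0
        assert max_evaporation(10.0, 33.6, 1.583836995987911, 0.175) \
            == pytest.approx(6.331365474577361, rel=1e-9)

    def test_diffusion_loss(self):
        assert diffusion_loss(0.0, 100.0) == pytest.approx(6.0)      # 6% of E_max
        assert diffusion_loss(100.0, 100.0) == 0.0                   # fully wetted
        assert diffusion_loss(50.0, 100.0) == pytest.approx(3.0, rel=1e-9)
        assert diffusion_loss(0.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            diffusion_loss(101.0, 100.0)

    def test_skin_evaporation_bounds(self):
        assert skin_evaporation(0.0, 100.0) == pytest.approx(6.0)
        assert skin_evaporation(100.0, 100.0) == pytest.approx(100.0)
        e = [skin_evaporation(x, 100.0) for x in (0.0, 25.0, 50.0, 100.0)]
        assert all(b > a for a, b in zip(e, e[1:]))
        assert all(x <= 100.0 + 1e-12 for x in e)


class TestBareSkinPath:
    def test_total_coefficient_oracle(self):
        assert total_heat_transfer_coefficient(1.0, 3.0, 4.5, 1.08) \
            == pytest.approx(3.5912214586566176, rel=1e-9)

    def test_nude_limit(self):
        assert total_heat_transfer_coefficient(0.0, 3.0, 4.5, 1.0) \
            == pytest.approx(7.5)

    def test_infinite_insulation_limit(self):
        assert total_heat_transfer_coefficient(1e9, 3.0, 4.5, 1.0) \
            == pytest.approx(0.0, abs=1e-6)

    def test_sensible_exchange(self):
        assert sensible_exchange_bare(23.1, 23.1, 7.5, 0.14) == 0.0
        assert sensible_exchange_bare(35.6, 23.1, 7.5, 0.140) \
            == pytest.approx(13.125, rel=1e-9)
        assert sensible_exchange_bare(35.6, 23.1, 7.5, 0.280) \
            == pytest.approx(26.25, rel=1e-9)

    def test_operative_temperature(self):
        assert operative_temperature(25.0, 25.0, 3.0, 4.5) == 25.0
        assert operative_temperature(25.0, 20.0, 3.0, 0.0) == 25.0
        assert operative_temperature(25.0, 20.0, 3.0, 4.5) == pytest.approx(22.0)


class TestGapConvection:
    def test_rayleigh_zero_and_cubic_scaling(self):
        assert rayleigh_number(0.0, 0.01, AIR) == 0.0
        r1 = rayleigh_number(2.0, 0.01, AIR)
        assert rayleigh_number(2.0, 0.02, AIR) == pytest.approx(8 * r1, rel=1e-12)

    def test_rayleigh_oracle_near_onset(self):
        # 3 K across a 15 mm gap sits just below the 10^3 threshold
        assert rayleigh_number(3.0, 0.015, AIR) == pytest.approx(
            926.0541220893643, rel=1e-9)

    def test_nusselt_conduction_branch(self):
        assert nusselt_enclosure(500.0, 0.71, 30.0) == 1.0
        assert nusselt_enclosure(0.0, 0.71, 30.0) == 1.0

    def test_nusselt_convective_oracle(self):
        assert nusselt_enclosure(1e6, 0.71, 30.0) == pytest.approx(
            4.197233349530367, rel=1e-9)

    def test_nusselt_floor_and_range(self):
        ras = np.geomspace(1.0, 1e10, 40)
        nus = nusselt_enclosure(ras, AIR.Pr, 30.0)
        assert np.all(nus >= 1.0)
        with pytest.raises(ValueError, match="correlation range"):
            nusselt_enclosure(2e10, 0.71, 30.0)

    def test_gap_coefficient(self):
        assert gap_coefficient(1.0, 0.026, 0.005) == pytest.approx(5.2, rel=1e-12)
        assert gap_coefficient(1.0, 0.026, 0.0195) == pytest.approx(
            1.3333333333333335, rel=1e-12)
        h1 = gap_coefficient(1.0, 0.026, 0.01)
        assert gap_coefficient(1.0, 0.026, 0.005) == pytest.approx(2 * h1)


class TestRadiantExchange:
    def test_black_body_factor(self):
        assert radiant_exchange_factor(1.0, 1.0) == 1.0

    def test_skin_to_inner_oracle(self):
        conv, rad = skin_to_inner_flux(33.6, 31.5, 5.2, 0.175, 0.95, 0.9,
                                       SIGMA, split=True)
        assert conv == pytest.approx(1.9110000000000011, rel=1e-9)
        assert rad == pytest.approx(2.0462728641659336, rel=1e-9)
        assert skin_to_inner_flux(33.6, 31.5, 5.2, 0.175, 0.95, 0.9, SIGMA) \
            == pytest.approx(conv + rad, rel=1e-12)

    def test_zero_at_equal_temperatures(self):
        assert skin_to_inner_flux(31.5, 31.5, 5.2, 0.175) == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.0, max_value=45.0),
           st.floats(min_value=0.0, max_value=45.0))
    def test_radiant_antisymmetry(self, a, b):
        _, r1 = skin_to_inner_flux(a, b, 5.0, 0.2, split=True)
        _, r2 = skin_to_inner_flux(b, a, 5.0, 0.2, split=True)
        assert r1 == pytest.approx(-r2, rel=1e-9, abs=1e-12)


class TestFabricAndOuterSurface:
    def test_fabric_flux(self):
        assert fabric_flux(30.0, 30.0, 0.024025, 0.1886) == 0.0
        assert fabric_flux(31.5, 29.2, 0.024025, 0.1886) == pytest.approx(
            18.055359001040586, rel=1e-9)
        assert fabric_flux(31.5, 29.2, 0.024025, 2 * 0.1886) == pytest.approx(
            2 * 18.055359001040586, rel=1e-9)

    def test_outer_coefficient_zero_and_scaling(self):
        assert outer_convective_coefficient(25.0, 25.0, 0.55, AIR) == 0.0
        h1 = outer_convective_coefficient(26.0, 25.0, 0.55, AIR)
        h16 = outer_convective_coefficient(41.0, 25.0, 0.55, AIR)
        assert h16 == pytest.approx(2 * h1, rel=1e-9)

    def test_outer_coefficient_oracle(self):
        assert outer_convective_coefficient(29.2, 25.0, 0.5504, AIR) \
            == pytest.approx(2.2144535747579663, rel=1e-9)

    def test_outer_flux_oracle_and_limits(self):
        assert outer_to_env_flux(25.0, 25.0, 25.0, 2.0, 0.9, SIGMA, 0.19) == 0.0
        conv, rad = outer_to_env_flux(29.2, 25.0, 20.0, 2.2144535747579663,
                                      0.9, SIGMA, 0.1886, split=True)
        # summed-parts oracle, plain arithmetic
        assert conv == pytest.approx(0.1886 * 2.2144535747579663 * 4.2, rel=1e-9)
        assert rad == pytest.approx(
            0.1886 * SIGMA * 0.9 * ((29.2 + KELVIN) ** 4 - (20.0 + KELVIN) ** 4),
            rel=1e-9)
        _, rad0 = outer_to_env_flux(29.2, 25.0, 20.0, 2.0, 0.0, SIGMA, 0.19,
                                    split=True)
        assert rad0 == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.0, max_value=45.0),
           st.floats(min_value=0.0, max_value=45.0))
    def test_outer_radiant_antisymmetry(self, a, b):
        _, r1 = outer_to_env_flux(a, 25.0, b, 2.0, 0.9, SIGMA, 0.19, split=True)
        _, r2 = outer_to_env_flux(b, 25.0, a, 2.0, 0.9, SIGMA, 0.19, split=True)
        assert r1 == pytest.approx(-r2, rel=1e-9, abs=1e-12)


class TestClothingBalances:
    def test_derivatives_consistent_with_fluxes(self, registry):
        scen = tc.load_reference_scenario("B", registry=registry)
        state = tc.initial_state(registry)
        dT5, dT6, diag = clothing_derivatives(state, scen.garment,
                                              scen.environment, registry,
                                              surface=scen.surface)
        m = registry.clothed
        np.testing.assert_allclose(
            dT5[m], (diag["Q_nc"][m] - diag["Q_f"][m]) / diag["C_inner"][m],
            rtol=1e-12)
        np.testing.assert_allclose(
            dT6[m], (diag["Q_f"][m] - diag["Q_a"][m]) / diag["C_outer"][m],
            rtol=1e-12)
        assert np.all(np.isnan(dT5[~m]))

    def test_inner_capacity_scales_with_gap(self, registry):
        scen = tc.load_reference_scenario("A", registry=registry)
        big = Garment.uniform(0.010, registry, scen.garment.fabric)
        state = tc.initial_state(registry)
        _, _, d1 = clothing_derivatives(state, scen.garment, scen.environment,
                                        registry)
        _, _, d2 = clothing_derivatives(state, big, scen.environment, registry)
        m = registry.clothed
        np.testing.assert_allclose(d2["C_inner"][m], 2 * d1["C_inner"][m],
                                   rtol=1e-12)

    def test_missing_gap_on_clothed_segment_rejected(self, registry):
        fab = Fabric()
        gap = np.full(16, np.nan)
        garment = Garment(gap=gap, fabric=fab, f_cl=registry.A_cl / registry.A_n)
        with pytest.raises(ValueError, match="air-gap"):
            garment.validate_clothed(registry.clothed)
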