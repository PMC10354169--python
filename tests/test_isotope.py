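"""Isotope notation conversions and gas-phase arithmetic."""
import math

import pytest
from hypothesis import given, strategies as st

from cryotrace import (
    HeadspaceObservation,
    IsotopeValue,
    atom_fraction_to_delta,
    atom_percent_excess,
    delta_to_atom_fraction,
    ppm_to_mass_c,
    respiration_rate,
    water_and_label_addition,
    water_content,
)
from cryotrace.config import R13_VPDB, Settings
from cryotrace.errors import DomainError, InvalidIsotopeValueError
from cryotrace.isotope import final_water_at_percent

NO_SOIL_VOLUME = Settings(bulk_density=None)


class TestDeltaConversion:
    def test_delta_zero_equals_standard_composition(self):
        # hand evaluation of R/(1+R) for the VPDB ratio
        assert delta_to_atom_fraction(0.0, 0.0111802) == pytest.approx(
            0.0110566, abs=5e-8
        )

    def test_depleted_limit_rejected(self):
        with pytest.raises(InvalidIsotopeValueError):
            delta_to_atom_fraction(-1000.0, R13_VPDB)

    @pytest.mark.parametrize("delta", [-50.0, 0.0, 500.0])
    def test_round_trip_at_reference_points(self, delta):
        af = delta_to_atom_fraction(delta, R13_VPDB)
        assert atom_fraction_to_delta(af, R13_VPDB) == pytest.approx(delta, abs=1e-9)

    @given(st.floats(min_value=-900.0, max_value=10000.0))
    def test_round_trip_is_identity(self, delta):
        af = delta_to_atom_fraction(delta, R13_VPDB)
        back = atom_fraction_to_delta(af, R13_VPDB)
        assert math.isclose(back, delta, rel_tol=1e-12, abs_tol=1e-9)

    def test_isotope_value_notations_agree(self):
        delta = IsotopeValue("delta_permil", -26.0)
        ap = IsotopeValue("atom_percent", delta.as_atom_percent())
        assert ap.as_delta() == pytest.approx(-26.0, abs=1e-9)
        with pytest.raises(InvalidIsotopeValueError):
            IsotopeValue("atom_fraction", 1.5)


class TestAtomPercentExcess:
    @pytest.mark.parametrize(
        "sample,control,expected,flagged",
        [(0.70, 0.20, 0.50, False), (0.20, 0.20, 0.0, False), (0.19, 0.20, 0.0, True)],
    )
    def test_excess_and_below_background_clipping(self, sample, control, expected, flagged):
        res = atom_percent_excess(sample, control)
        assert res.value == pytest.approx(expected)
        assert res.below_background is flagged
        if flagged:
            assert res.raw_difference == pytest.approx(sample - control)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidIsotopeValueError):
            atom_percent_excess(101.0, 0.2)


class TestPpmToMassC:
    def test_ideal_gas_oracle(self):
        # n_air = 0.027 / (0.082057 * 284.15) mol; 400 ppm thereof as C
        assert ppm_to_mass_c(400.0, 27.0, 11.0) == pytest.approx(5.57, abs=0.01)

    def test_zero_and_linearity(self):
        assert ppm_to_mass_c(0.0, 27.0, 11.0) == 0.0
        assert ppm_to_mass_c(800.0, 27.0, 11.0) == pytest.approx(
            2 * ppm_to_mass_c(400.0, 27.0, 11.0)
        )

    @given(
        st.floats(min_value=1.0, max_value=5000.0),
        st.floats(min_value=1.0, max_value=100.0),
        st.floats(min_value=-5.0, max_value=40.0),
    )
    def test_linear_in_volume_decreasing_in_temperature(self, ppm, vol, temp):
        assert ppm_to_mass_c(ppm, 2 * vol, temp) == pytest.approx(
            2 * ppm_to_mass_c(ppm, vol, temp), rel=1e-12
        )
        assert ppm_to_mass_c(ppm, vol, temp + 5.0) < ppm_to_mass_c(ppm, vol, temp)

    def test_nonphysical_inputs_rejected(self):
        with pytest.raises(DomainError):
            ppm_to_mass_c(400.0, -1.0, 11.0)
        with pytest.raises(DomainError):
            ppm_to_mass_c(400.0, 27.0, -300.0)


def _obs(**kw):
    base = dict(
        vial_volume_ml=27.0,
        soil_fresh_mass_g=1.0,
        dry_mass_fraction=1.0,
        co2_ppm_t0=400.0,
        co2_ppm_t1=600.0,
        duration_h=42.0,
        temperature_c=11.0,
    )
    base.update(kw)
    return HeadspaceObservation(**base)


class TestRespirationRate:
    def test_steady_state_without_sampling_is_zero(self):
        res = respiration_rate(_obs(co2_ppm_t1=400.0), NO_SOIL_VOLUME)
        assert res.rate == pytest.approx(0.0, abs=1e-12)
        assert not res.negative

    def test_two_point_accumulation_oracle(self):
        # (mass(600) - mass(400)) / 42 h / 1 g via the ideal-gas oracle
        res = respiration_rate(_obs(), NO_SOIL_VOLUME)
        assert res.rate == pytest.approx(66.3, abs=0.5)

    def test_replacement_mass_balance_zero_rate(self):
        # CO2-free replacement air: if t1 equals the post-sampling level,
        # no CO2 was produced
        sampled = 5.0
        obs = _obs(
            sampled_volume_ml=sampled,
            replacement_co2_ppm=0.0,
            co2_ppm_t1=400.0 * (1 - sampled / 27.0),
        )
        res = respiration_rate(obs, NO_SOIL_VOLUME)
        assert res.rate == pytest.approx(0.0, abs=1e-9)

    def test_negative_rate_flagged_not_clipped(self):
        res = respiration_rate(_obs(co2_ppm_t1=300.0), NO_SOIL_VOLUME)
        assert res.rate < 0
        assert res.negative

    @given(
        st.floats(min_value=400.0, max_value=800.0),
        st.floats(min_value=800.0, max_value=2000.0),
    )
    def test_window_splitting_additivity(self, mid, end):
        """An intermediate measurement without sampling changes nothing."""
        full = respiration_rate(_obs(co2_ppm_t1=end), NO_SOIL_VOLUME).rate
        first = respiration_rate(
            _obs(co2_ppm_t1=mid, duration_h=21.0), NO_SOIL_VOLUME
        ).rate
        second = respiration_rate(
            _obs(co2_ppm_t0=mid, co2_ppm_t1=end, duration_h=21.0), NO_SOIL_VOLUME
        ).rate
        assert full == pytest.approx((first + second) / 2, rel=1e-9)

    def test_soil_volume_correction_shrinks_headspace(self):
        uncorrected = respiration_rate(_obs(), NO_SOIL_VOLUME).rate
        corrected = respiration_rate(_obs(), Settings(bulk_density=1.3)).rate
        assert corrected < uncorrected


class TestWaterAddition:
    def test_stock_enrichment_algebraic_oracle(self):
        res = water_and_label_addition(0.12, 0.40, 0.6, 20.0, 0.2)
        assert res.water_to_add == pytest.approx(0.12)
        assert res.required_stock_at_percent == pytest.approx(39.8, abs=1e-9)

    def test_no_enrichment_degenerate_case(self):
        res = water_and_label_addition(0.12, 0.40, 0.6, 0.2, 0.2)
        assert res.required_stock_at_percent == pytest.approx(0.2)

    def test_already_wet_soil_rejected(self):
        with pytest.raises(DomainError):
            water_and_label_addition(0.24, 0.40, 0.6, 20.0, 0.2)

    @given(
        st.floats(min_value=0.01, max_value=0.2),
        st.floats(min_value=0.35, max_value=0.9),
        st.floats(min_value=1.0, max_value=50.0),
    )
    def test_forward_mixing_reproduces_target(self, current, whc, target_at):
        res = water_and_label_addition(current, whc, 0.6, target_at, 0.2)
        final = final_water_at_percent(
            current, res.water_to_add, res.required_stock_at_percent, 0.2
        )
        assert final == pytest.approx(target_at, abs=1e-10)


class TestWaterContent:
    @pytest.mark.parametrize(
        "fresh,dry,expected", [(6.0, 5.0, 0.20), (5.0, 5.0, 0.0), (12.08, 10.0, 0.208)]
    )
    def test_gravimetric_fraction_of_dry_soil(self, fresh, dry, expected):
        assert water_content(fresh, dry) == pytest.approx(expected)

    def test_invalid_masses_rejected(self):
        with pytest.raises(DomainError):
            water_content(5.0, 0.0)
        with pytest.raises(DomainError):
            water_content(5.0, 6.0)
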