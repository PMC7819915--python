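"""Mass-balance inversion, energy conversions and conductance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from thermoresp import (
    GasSample,
    ehl_from_ewl,
    excurrent_sample,
    gas_exchange_rates,
    metabolic_rate,
    respiratory_exchange_ratio,
    surface_area,
    thermal_conductance,
)

MODES = ["push_chamber", "pull_mask", "pull_chamber"]


class TestGasExchange:
    def test_baseline_air_gives_zero_rates(self):
        s = GasSample(feo2=0.2095, feco2=0.0, ph2o=0.0, flow=500.0)
        r = gas_exchange_rates(s)
        assert r.vo2 == pytest.approx(0.0, abs=1e-12)
        assert r.vco2 == pytest.approx(0.0, abs=1e-12)
        assert r.ewl == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "mode,vo2,vco2,ewl",
        [
            ("push_chamber", 0.70, 0.60, 1.5),
            ("pull_mask", 1.0, 0.85, 3.0),
            ("pull_chamber", 0.0, 0.0, 1.0),
        ],
    )
    def test_inverts_forward_mass_balance(self, mode, vo2, vco2, ewl):
        s = excurrent_sample(vo2, vco2, ewl, flow=500.0, mode=mode)
        r = gas_exchange_rates(s)
        assert r.vo2 == pytest.approx(vo2, rel=1e-6, abs=1e-9)
        assert r.vco2 == pytest.approx(vco2, rel=1e-6, abs=1e-9)
        assert r.ewl == pytest.approx(ewl, rel=1e-6, abs=1e-9)

    @given(
        vo2=st.floats(0.1, 2.0),
        rer=st.floats(0.7, 1.0),
        ewl=st.floats(0.0, 10.0),
        flow=st.floats(200.0, 500.0),
        mode=st.sampled_from(MODES),
    )
    def test_inversion_property(self, vo2, rer, ewl, flow, mode):
        s = excurrent_sample(vo2, rer * vo2, ewl, flow=flow, mode=mode)
        r = gas_exchange_rates(s)
        assert abs(r.vo2 - vo2) <= 1e-6 * vo2
        assert abs(r.vco2 - rer * vo2) <= 1e-6 * rer * vo2
        assert abs(r.ewl - ewl) <= 1e-6 * max(ewl, 1.0)

    def test_humid_incurrent_air_round_trips(self):
        s = excurrent_sample(0.8, 0.7, 2.0, flow=400.0, mode="push_chamber", pih2o=1.0)
        r = gas_exchange_rates(s)
        assert r.vo2 == pytest.approx(0.8, rel=1e-9)
        assert r.ewl == pytest.approx(2.0, rel=1e-9)

    def test_tiny_negative_rate_zeroed_with_warning(self):
        s = excurrent_sample(0.0, 0.0, 0.0, flow=500.0)
        s.feo2 += 1e-8  # slightly above incurrent: small negative vo2
        with pytest.warns(UserWarning, match="slightly negative"):
            r = gas_exchange_rates(s)
        assert r.vo2 == 0.0
        assert not r.flagged

    def test_large_negative_rate_flagged_not_clamped(self):
        s = GasSample(feo2=0.2150, feco2=0.0, ph2o=0.0, flow=500.0)
        r = gas_exchange_rates(s)
        assert r.flagged
        assert r.vo2 < -0.01

    def test_water_pressure_above_barometric_rejected(self):
        with pytest.raises(ValueError, match="barometric"):
            GasSample(feo2=0.2, feco2=0.0, ph2o=102.0, flow=500.0)

    def test_bad_mode_and_flow_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            GasSample(feo2=0.2, feco2=0.0, ph2o=0.0, flow=500.0, mode="push_mask")
        with pytest.raises(ValueError, match="flow"):
            GasSample(feo2=0.2, feco2=0.0, ph2o=0.0, flow=0.0)


class TestConversions:
    def test_rer(self):
        assert respiratory_exchange_ratio(1.0, 0.85) == pytest.approx(0.85)
        assert respiratory_exchange_ratio(2.0, 2.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            respiratory_exchange_ratio(0.0, 0.5)

    @pytest.mark.parametrize(
        "vo2,rer,expected",
        [
            (0.0, 0.8, 0.0),
            (1.0, 0.7, 0.32691333),  # (16 + 5.164*0.7)/60
            (0.68, 1.0, 0.23985867),  # 0.68*21.164/60 ~ basal level of a 15 g bird
        ],
    )
    def test_oxyjoule_metabolic_rate(self, vo2, rer, expected):
        assert metabolic_rate(vo2, rer) == pytest.approx(expected, abs=1e-6)

    def test_metabolic_rate_linear_in_vo2_increasing_in_rer(self):
        assert metabolic_rate(2.0, 0.8) == pytest.approx(2 * metabolic_rate(1.0, 0.8))
        assert metabolic_rate(1.0, 0.9) > metabolic_rate(1.0, 0.8)
        with pytest.raises(ValueError):
            metabolic_rate(-0.1, 0.8)

    def test_rer_outside_physiological_range_warns(self):
        with pytest.warns(UserWarning, match="RER"):
            metabolic_rate(1.0, 1.3)

    @pytest.mark.parametrize(
        "ewl,expected", [(0.0, 0.0), (25.0, 1.0), (1.525, 0.061)]
    )
    def test_latent_heat_conversion(self, ewl, expected):
        assert ehl_from_ewl(ewl) == pytest.approx(expected, abs=1e-9)
        with pytest.raises(ValueError):
            ehl_from_ewl(-1.0)

    @pytest.mark.parametrize(
        "mb,expected", [(1.0, 10.0), (8.0, 40.0277), (15.0, 60.8769)]
    )
    def test_surface_area_allometry(self, mb, expected):
        assert surface_area(mb) == pytest.approx(expected, rel=1e-4)

    def test_surface_area_monotone_and_positive_domain(self):
        assert surface_area(20.0) > surface_area(10.0) > surface_area(5.0)
        with pytest.raises(ValueError):
            surface_area(0.0)


class TestConductance:
    def test_zero_when_dry_heat_production_zero(self):
        assert thermal_conductance(0.06, 0.06, 41.0, 23.0, 15.0) == 0.0

    def test_hand_computed_value(self):
        # (0.30-0.06)/((41-23)*60.877) = 2.19e-4 W/degC/cm2
        c = thermal_conductance(0.30, 0.06, 41.0, 23.0, 15.0)
        assert c == pytest.approx(2.1902e-4, rel=1e-3)
        assert c * 1000 == pytest.approx(0.219, rel=1e-2)  # display scale

    def test_out_of_domain_raises(self):
        with pytest.raises(ValueError, match="tb > ta"):
            thermal_conductance(0.30, 0.06, 23.0, 41.0, 15.0)

    @given(k=st.floats(-10.0, 10.0))
    def test_invariant_to_common_temperature_shift(self, k):
        base = thermal_conductance(0.3, 0.05, 41.0, 25.0, 12.0)
        shifted = thermal_conductance(0.3, 0.05, 41.0 + k, 25.0 + k, 12.0)
        assert shifted == pytest.approx(base, rel=1e-12)
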