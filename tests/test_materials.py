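"""Material property laws: sigma(T), effective heat, enthalpy, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from salinerf.materials import (LATENT_HEAT, RHO_WATER_99, calibrate_sigma37,
                                default_materials, effective_volumetric_heat,
                                electrical_conductivity)

MATS = default_materials(alpha=1.0)


class TestElectricalConductivity:
    @pytest.mark.parametrize("name,T,expected", [
        ("tissue", 37.0, 0.31),
        ("tissue", 47.0, 0.31 * 1.10),
        ("saline", 37.0, 0.774),
    ])
    def test_calibrated_values(self, name, T, expected):
        assert electrical_conductivity(name, T) == pytest.approx(expected, rel=1e-9)

    def test_unknown_material_rejected(self):
        with pytest.raises(KeyError):
            electrical_conductivity("butter", 37.0)

    def test_two_decade_fall_across_vaporization(self):
        s99 = MATS["tissue"].electrical_conductivity(99.0)
        s100 = MATS["tissue"].electrical_conductivity(100.0)
        assert s100 == pytest.approx(s99 * 1e-2)
        assert MATS["tissue"].electrical_conductivity(150.0) == pytest.approx(s100)

    @given(T=st.floats(0.0, 150.0))
    @settings(max_examples=200, deadline=None)
    def test_continuity(self, T):
        m = MATS["saline"]
        eps = 1e-7
        a, b = m.electrical_conductivity(T - eps), m.electrical_conductivity(T + eps)
        assert abs(a - b) < 1e-3 * m.sigma37

    def test_strictly_increasing_below_99(self):
        T = np.linspace(0.0, 99.0, 300)
        for name in ("tissue", "saline"):
            s = MATS[name].electrical_conductivity(T)
            assert (np.diff(s) > 0).all()

    def test_infinite_temperature_rejected(self):
        with pytest.raises(ValueError):
            MATS["tissue"].electrical_conductivity(np.inf)

    def test_calibration_anchored_at_measurement_temperature(self):
        # changing alpha must not change sigma at the calibration temperature
        for alpha in (1.0, 1.5, 2.0):
            m = default_materials(alpha)
            assert m["tissue"].electrical_conductivity(24.0) == \
                pytest.approx(0.31 * 0.87)
            assert m["saline"].electrical_conductivity(20.0) == \
                pytest.approx(0.774 * 0.83)


class TestEffectiveHeat:
    def test_liquid_phase_products(self):
        assert effective_volumetric_heat("tissue", 50.0) == \
            pytest.approx(1080.0 * 3455.0)
        assert effective_volumetric_heat("saline", 50.0) == \
            pytest.approx(1004.0 * 3200.0)
        assert effective_volumetric_heat("electrode", 500.0) == \
            pytest.approx(6450.0 * 840.0)

    def test_transition_band_latent_heat(self):
        # water latent heat times tissue water content over the 1 degC band
        assert effective_volumetric_heat("tissue", 99.5) == \
            pytest.approx(LATENT_HEAT * 0.68 * RHO_WATER_99)

    def test_tissue_gas_phase(self):
        assert effective_volumetric_heat("tissue", 101.0) == \
            pytest.approx(370.44 * 2155.0)

    def test_saline_transition_persists(self):
        # continuous resupply: the transition capacity is kept for all T >= 99
        assert effective_volumetric_heat("saline", 120.0) == \
            pytest.approx(effective_volumetric_heat("saline", 99.5))

    @pytest.mark.parametrize("name", ["tissue", "saline", "plastic", "electrode"])
    def test_enthalpy_strictly_increasing(self, name):
        T = np.linspace(-10.0, 180.0, 2000)
        h = MATS[name].enthalpy(T)
        assert (np.diff(h) > 0).all()

    def test_enthalpy_consistent_with_capacity(self):
        # h(T) integrates the effective volumetric heat
        m = MATS["tissue"]
        T = np.linspace(20.0, 150.0, 40000)
        h_num = np.concatenate([[0.0], np.cumsum(
            m.effective_volumetric_heat(0.5 * (T[1:] + T[:-1])) * np.diff(T))])
        assert np.allclose(h_num + m.enthalpy(T[0]), m.enthalpy(T), rtol=5e-3)


class TestCalibration:
    def test_inverse_proportionality(self):
        forward = lambda s: 100.0 * 0.3 / s  # Z ~ 1/sigma
        s1 = calibrate_sigma37(50.0, forward, 0.3)
        s2 = calibrate_sigma37(100.0, forward, 0.3)
        assert s1 == pytest.approx(2 * s2)
        assert forward(s1) == pytest.approx(50.0)

    def test_nonpositive_impedance_rejected(self):
        with pytest.raises(ValueError):
            calibrate_sigma37(0.0, lambda s: 1.0 / s, 0.3)
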