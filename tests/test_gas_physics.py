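"""Solubility, Schmidt numbers, k conversion and the vial mass balance.

The oracles here are deliberately independent re-implementations: the
solubility and Schmidt fits are re-transcribed from their published
coefficient tables with plain ``math`` arithmetic, and the vial round
trip is solved symbolically with sympy from the three governing
equations (Henry partitioning, ideal gas, mass conservation).
"""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from streamn2o.errors import RangeError, ValidationError
from streamn2o.gas_physics import (
    GasSample,
    dissolved_from_headspace,
    headspace_to_dissolved,
    k600_to_kgas,
    n2o_solubility,
    schmidt_number,
)


def _oracle_solubility_moist(t_c: float, s: float = 0.0) -> float:
    """Independent transcription of the published moist-air N2O fit."""
    t = (t_c + 273.15) / 100.0
    ln_f = (-165.8806 + 222.8743 / t + 92.0792 * math.log(t)
            - 1.48425 * t ** 2
            + s * (-0.056235 + 0.031619 * t - 0.0048472 * t ** 2))
    return math.exp(ln_f)


def _oracle_solubility_dry(t_c: float, s: float = 0.0) -> float:
    """Independent transcription of the published dry-gas K0 fit."""
    t = (t_c + 273.15) / 100.0
    ln_k = (-62.7062 + 97.3066 / t + 24.1406 * math.log(t)
            + s * (-0.058420 + 0.033193 * t - 0.0051313 * t ** 2))
    return math.exp(ln_k)


def _oracle_schmidt_n2o(t_c: float) -> float:
    """Hand Horner evaluation of the freshwater N2O Schmidt polynomial."""
    return (2141.2 + t_c * (-152.56 + t_c * (5.8963 + t_c * (
        -0.12411 + t_c * 0.0010655))))


class TestSolubility:
    @pytest.mark.parametrize("t_c", [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
    def test_matches_published_coefficient_set_to_4_sig_figs(self, t_c):
        for basis, oracle in (("moist_air", _oracle_solubility_moist),
                              ("dry_gas", _oracle_solubility_dry)):
            got = n2o_solubility(t_c, basis=basis)
            assert got == pytest.approx(oracle(t_c), rel=5e-4)

    def test_salinity_term_matches_oracle(self):
        got = n2o_solubility(20.0, salinity=35.0)
        assert got == pytest.approx(_oracle_solubility_moist(20.0, 35.0),
                                    rel=5e-4)

    def test_cold_water_holds_more_gas(self):
        assert n2o_solubility(5.0) > n2o_solubility(25.0)

    @given(st.floats(0.0, 34.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_temperature(self, t_c):
        assert n2o_solubility(t_c) > n2o_solubility(t_c + 0.5)

    def test_pure_function_determinism(self):
        assert n2o_solubility(20.0) == n2o_solubility(20.0)

    def test_out_of_range_temperature_names_the_limit(self):
        with pytest.raises(RangeError, match="40"):
            n2o_solubility(55.0)

    def test_negative_salinity_rejected(self):
        with pytest.raises(ValidationError):
            n2o_solubility(20.0, salinity=-1.0)


class TestSchmidt:
    def test_co2_reference_is_600_at_20c(self):
        assert schmidt_number(20.0, gas="CO2") == pytest.approx(600.0,
                                                                rel=1e-3)

    @pytest.mark.parametrize("t_c", [0.0, 10.0, 20.0, 30.0, 35.0])
    def test_matches_independent_polynomial_evaluation(self, t_c):
        assert schmidt_number(t_c) == pytest.approx(
            _oracle_schmidt_n2o(t_c), rel=5e-4)

    @given(st.floats(0.0, 34.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_decreasing_on_validity_range(self, t_c):
        assert schmidt_number(t_c) > schmidt_number(t_c + 1.0)

    def test_1992_set_is_selectable_and_close(self):
        sc14 = schmidt_number(20.0)
        sc92 = schmidt_number(20.0, coefficient_set="wanninkhof1992")
        assert sc14 != sc92
        assert sc92 == pytest.approx(sc14, rel=0.1)

    def test_out_of_range_temperature_raises(self):
        with pytest.raises(RangeError):
            schmidt_number(36.0)


class TestKConversion:
    def test_identity_where_schmidt_equals_600(self):
        # solve Sc_N2O(T) = 600 by bisection, then k must pass unchanged
        lo, hi = 15.0, 30.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if schmidt_number(mid) > 600.0:
                lo = mid
            else:
                hi = mid
        assert k600_to_kgas(7.31, (lo + hi) / 2) == pytest.approx(7.31,
                                                                  rel=1e-9)

    def test_zero_maps_to_zero(self):
        assert k600_to_kgas(0.0, 17.0) == 0.0

    def test_hand_computed_value_at_10c(self):
        expected = 10.0 * (_oracle_schmidt_n2o(10.0) / 600.0) ** -0.5
        assert k600_to_kgas(10.0, 10.0) == pytest.approx(expected, rel=1e-6)

    @given(st.floats(0.0, 50.0), st.floats(0.1, 10.0), st.floats(0.5, 34.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_homogeneous_of_degree_one_in_k600(self, k600, c, t_c):
        assert k600_to_kgas(c * k600, t_c) == pytest.approx(
            c * k600_to_kgas(k600, t_c), rel=1e-12, abs=1e-12)

    def test_negative_k600_rejected(self):
        with pytest.raises(ValidationError):
            k600_to_kgas(-1.0, 10.0)


def _sympy_vial_headspace_ppb(c_true_ug_l, t_c, p_atm, vial_ml, water_ml):
    """Forward-simulate the vial equilibrium with a symbolic solver.

    Unknowns: partial pressure p (atm) and dissolved concentration c
    (mol/L) after equilibration. Equations: Henry's law through the
    published solubility, and conservation of the N2O initially
    dissolved in the water aliquot (the vial starts N2O-free).
    """
    p, c = sympy.symbols("p c", positive=True)
    r_gas = 0.08205736
    t_k = t_c + 273.15
    vw, vh = water_ml / 1000.0, (vial_ml - water_ml) / 1000.0
    n_initial = c_true_ug_l * 1e-6 / 28.0 * vw
    k0 = _oracle_solubility_moist(t_c)
    solution = sympy.solve(
        [sympy.Eq(c, k0 * p),
         sympy.Eq(p * vh / (r_gas * t_k) + c * vw, n_initial)],
        [p, c], dict=True)[0]
    return float(solution[p]) / (1e-9 * p_atm)


class TestHeadspaceMassBalance:
    def test_empty_headspace_means_zero_dissolved(self):
        sample = GasSample("s0", water_temp=10.0, pressure=1.0,
                           headspace_ppb=0.0, vial_volume=22.5,
                           water_volume=10.0)
        assert headspace_to_dissolved(sample) == 0.0

    @pytest.mark.parametrize("c_true, t_c, p_atm, vial, water", [
        (1.3, 10.0, 1.0, 22.5, 10.0),
        (0.2, 2.0, 0.97, 60.0, 15.0),
        (19.6, 20.0, 1.02, 20.0, 5.0),
    ])
    def test_round_trip_against_symbolic_partition_oracle(
            self, c_true, t_c, p_atm, vial, water):
        ppb = _sympy_vial_headspace_ppb(c_true, t_c, p_atm, vial, water)
        sample = GasSample("rt", water_temp=t_c, pressure=p_atm,
                           headspace_ppb=ppb, vial_volume=vial,
                           water_volume=water)
        assert headspace_to_dissolved(sample) == pytest.approx(c_true,
                                                               rel=1e-9)

    def test_linear_in_headspace_mixing_ratio(self):
        base = dict(water_temp=8.0, pressure=1.0, vial_volume=22.5,
                    water_volume=10.0)
        c1 = headspace_to_dissolved(GasSample("a", headspace_ppb=500.0, **base))
        c2 = headspace_to_dissolved(GasSample("b", headspace_ppb=1000.0, **base))
        assert c2 == pytest.approx(2.0 * c1, rel=1e-12)

    @given(
        ppb=st.floats(0.0, 1e5),
        t_c=st.floats(0.5, 34.0),
        p=st.floats(0.9, 1.1),
        water=st.floats(2.0, 18.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mass_conservation(self, ppb, t_c, p, water):
        """Headspace + dissolved-at-equilibrium moles equal C_obs*Vw/28."""
        vial = 22.5
        c_obs = dissolved_from_headspace(ppb, t_c, p, vial, water)
        partial = ppb * 1e-9 * p
        mol_head = partial * (vial - water) / 1000.0 \
            / (0.08205736 * (t_c + 273.15))
        mol_diss = n2o_solubility(t_c) * partial * water / 1000.0
        lhs = mol_head + mol_diss
        rhs = c_obs * 1e-6 / 28.0 * water / 1000.0
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-30)

    def test_equilibration_temperature_defaults_to_stream_water(self):
        s = GasSample("d", water_temp=12.5, pressure=1.0, headspace_ppb=900.0,
                      vial_volume=22.5, water_volume=10.0)
        assert s.equilibration_temp == 12.5
        assert s.headspace_volume == pytest.approx(12.5)

    @pytest.mark.parametrize("kwargs", [
        dict(water_volume=0.0),
        dict(water_volume=30.0),
        dict(headspace_ppb=-1.0),
        dict(pressure=0.0),
        dict(water_temp=55.0),
    ])
    def test_invalid_samples_rejected(self, kwargs):
        base = dict(water_temp=10.0, pressure=1.0, headspace_ppb=100.0,
                    vial_volume=22.5, water_volume=10.0)
        base.update(kwargs)
        with pytest.raises(ValidationError):
            GasSample("bad", **base)
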