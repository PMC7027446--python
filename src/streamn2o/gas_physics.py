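"""Temperature- and pressure-dependent gas chemistry for dissolved N2O.

This module collects the physical-chemistry primitives the rest of the
package builds on:

* Henry's-law-type solubility of N2O in water after Weiss & Price (1980),
  either referenced to moist air at 1 atm total pressure (the default,
  appropriate when working from atmospheric mixing ratios) or to the dry
  gas partial pressure.
* Schmidt numbers for N2O and CO2 in fresh water from the Wanninkhof
  polynomial fits (2014 coefficients by default, 1992 selectable).
* Conversion of a CO2-normalised gas transfer velocity (k600) to the
  N2O-specific velocity via the Schmidt-number scaling (Sc/600)^-0.5.
* The headspace-vial mass balance that recovers the dissolved N2O
  concentration of a water sample from the mixing ratio measured by gas
  chromatography in the equilibrated vial headspace.

All concentrations are expressed as micrograms of N2O-bound nitrogen per
litre (ug N/L; 28 g N per mol N2O, two N atoms per molecule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import RangeError, ValidationError

# Ideal-gas constant in vial-friendly units.
R_L_ATM_PER_MOL_K = 0.08205736  # L atm mol-1 K-1
CELSIUS_OFFSET = 273.15

# Molar masses used throughout; the N basis carries both N atoms of N2O.
GRAMS_N_PER_MOL_N2O = 28.0
GRAMS_N2O_PER_MOL = 44.0

# Reference Schmidt number of the k600 convention (CO2 at 20 C, fresh water).
SCHMIDT_REFERENCE = 600.0


@dataclass(frozen=True)
class SolubilityModel:
    """A published ln-polynomial solubility fit for one gas.

    ln K0 = a0 + a1*(100/T) + a2*ln(T/100) + a3*(T/100)^2
            + S * (b0 + b1*(T/100) + b2*(T/100)^2)

    with T in kelvin, S in per mil, and K0 in mol L-1 atm-1.
    """

    gas: str
    basis: str
    a: tuple[float, float, float, float]
    b: tuple[float, float, float]
    valid_t_range: tuple[float, float] = (-0.5, 40.0)

    def k0(self, temp_c, salinity=0.0):
        temp_c = np.asarray(temp_c, dtype=float)
        lo, hi = self.valid_t_range
        if np.any(temp_c < lo) or np.any(temp_c > hi):
            raise RangeError(
                f"temperature outside the {self.gas} solubility fit range "
                f"[{lo}, {hi}] C"
            )
        salinity = np.asarray(salinity, dtype=float)
        if np.any(salinity < 0):
            raise ValidationError("salinity must be >= 0 per mil")
        t_k = temp_c + CELSIUS_OFFSET
        t100 = t_k / 100.0
        a0, a1, a2, a3 = self.a
        b0, b1, b2 = self.b
        ln_k0 = (
            a0
            + a1 / t100
            + a2 * np.log(t100)
            + a3 * t100 * t100
            + salinity * (b0 + b1 * t100 + b2 * t100 * t100)
        )
        out = np.exp(ln_k0)
        return float(out) if out.ndim == 0 else out


#: Weiss & Price (1980) N2O coefficient sets, mol L-1 atm-1.
#: "moist_air" is the F-style function referenced to the mixing ratio in
#: water-vapour-saturated air at 1 atm total pressure; "dry_gas" is the
#: classic K0 referenced to the dry partial pressure.
N2O_SOLUBILITY_MODELS = {
    "moist_air": SolubilityModel(
        gas="N2O",
        basis="moist_air",
        a=(-165.8806, 222.8743, 92.0792, -1.48425),
        b=(-0.056235, 0.031619, -0.0048472),
    ),
    "dry_gas": SolubilityModel(
        gas="N2O",
        basis="dry_gas",
        a=(-62.7062, 97.3066, 24.1406, 0.0),
        b=(-0.058420, 0.033193, -0.0051313),
    ),
}

DEFAULT_SOLUBILITY_BASIS = "moist_air"


def n2o_solubility(temp_c, salinity=0.0, basis: str = DEFAULT_SOLUBILITY_BASIS):
    """N2O solubility K0 in mol L-1 atm-1 at ``temp_c`` (C).

    ``basis`` selects the moist-air-referenced function (default; multiply
    by mixing ratio x total pressure to get the equilibrium concentration)
    or the dry-gas-partial-pressure K0. Fresh water is ``salinity=0``.
    """
    try:
        model = N2O_SOLUBILITY_MODELS[basis]
    except KeyError:
        raise ValidationError(
            f"unknown solubility basis {basis!r}; "
            f"expected one of {sorted(N2O_SOLUBILITY_MODELS)}"
        ) from None
    return model.k0(temp_c, salinity)


#: Freshwater Schmidt-number polynomials Sc(t) = c0 + c1 t + c2 t^2 + ...
#: with t in C. Keyed by coefficient-set id, then gas.
SCHMIDT_COEFFICIENTS = {
    "wanninkhof2014": {
        "N2O": (2141.2, -152.56, 5.8963, -0.12411, 0.0010655),
        "CO2": (1923.6, -125.06, 4.3773, -0.085681, 0.00070284),
    },
    "wanninkhof1992": {
        "N2O": (2055.6, -137.11, 4.3173, -0.054350),
        "CO2": (1911.1, -118.11, 3.4527, -0.041320),
    },
}

DEFAULT_SCHMIDT_SET = "wanninkhof2014"
SCHMIDT_T_RANGE = (0.0, 35.0)


def schmidt_number(temp_c, gas: str = "N2O",
                   coefficient_set: str = DEFAULT_SCHMIDT_SET):
    """Freshwater Schmidt number of ``gas`` at ``temp_c`` (C).

    Valid on 0-35 C, the range of the published polynomial fits; the
    CO2 set evaluates to ~600 at 20 C, anchoring the k600 convention.
    """
    try:
        coeffs = SCHMIDT_COEFFICIENTS[coefficient_set][gas]
    except KeyError:
        raise ValidationError(
            f"no Schmidt coefficients for gas={gas!r} in set "
            f"{coefficient_set!r}"
        ) from None
    temp_c = np.asarray(temp_c, dtype=float)
    lo, hi = SCHMIDT_T_RANGE
    if np.any(temp_c < lo) or np.any(temp_c > hi):
        raise RangeError(
            f"temperature outside the Schmidt polynomial range [{lo}, {hi}] C"
        )
    out = np.polynomial.polynomial.polyval(temp_c, np.asarray(coeffs))
    return float(out) if out.ndim == 0 else out


def k600_to_kgas(k600, temp_c, gas: str = "N2O",
                 coefficient_set: str = DEFAULT_SCHMIDT_SET):
    """Convert k600 (m/day) to the gas-specific transfer velocity.

    k_gas = k600 * (Sc_gas(T)/600)^-0.5. Homogeneous of degree one in
    ``k600``; zero maps to zero.
    """
    k600 = np.asarray(k600, dtype=float)
    if np.any(k600 < 0):
        raise ValidationError("k600 must be >= 0 m/day")
    sc = schmidt_number(temp_c, gas=gas, coefficient_set=coefficient_set)
    out = k600 * (np.asarray(sc) / SCHMIDT_REFERENCE) ** -0.5
    return float(out) if out.ndim == 0 else out


@dataclass
class GasSample:
    """One field vial: the inputs needed to recover dissolved N2O.

    The vial is assumed preflushed with N2 (zero initial headspace N2O)
    and equilibrated at ``equilibration_temp`` (defaults to the stream
    water temperature) under total pressure ``pressure``. ``headspace_ppb``
    is the N2O mixing ratio measured by GC in the equilibrated headspace,
    interpreted as nmol per mol of moist headspace gas at total pressure.
    """

    sample_id: str
    water_temp: float  # C
    pressure: float  # atm
    headspace_ppb: float
    vial_volume: float  # mL
    water_volume: float  # mL
    equilibration_temp: Optional[float] = None
    region_id: str = ""
    site_id: str = ""
    date: str = ""

    def __post_init__(self):
        if self.equilibration_temp is None:
            self.equilibration_temp = self.water_temp
        if not 0.0 < self.water_volume < self.vial_volume:
            raise ValidationError(
                f"sample {self.sample_id}: need 0 < water_volume "
                f"< vial_volume, got {self.water_volume} / {self.vial_volume} mL"
            )
        if self.headspace_ppb < 0:
            raise ValidationError(
                f"sample {self.sample_id}: headspace_ppb must be >= 0"
            )
        if self.pressure <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: pressure must be > 0 atm"
            )
        for label, temp in (("water_temp", self.water_temp),
                            ("equilibration_temp", self.equilibration_temp)):
            if not -5.0 <= temp <= 40.0:
                raise ValidationError(
                    f"sample {self.sample_id}: {label}={temp} C outside [-5, 40]"
                )

    @property
    def headspace_volume(self) -> float:
        """Headspace volume in mL (vial minus water)."""
        return self.vial_volume - self.water_volume


def dissolved_from_headspace(headspace_ppb, equilibration_temp_c, pressure_atm,
                             vial_volume_ml, water_volume_ml,
                             basis: str = DEFAULT_SOLUBILITY_BASIS):
    """Vectorised headspace mass balance; returns C_obs in ug N/L.

    Moles of N2O found in the equilibrated headspace (ideal gas at the
    equilibration temperature and vial pressure) plus moles still
    dissolved at equilibrium (Henry partitioning via the solubility
    function) are attributed to the original water aliquot.
    """
    headspace_ppb = np.asarray(headspace_ppb, dtype=float)
    pressure_atm = np.asarray(pressure_atm, dtype=float)
    vial_volume_ml = np.asarray(vial_volume_ml, dtype=float)
    water_volume_ml = np.asarray(water_volume_ml, dtype=float)
    if np.any(water_volume_ml <= 0):
        raise ValidationError("water_volume must be > 0 mL")
    if np.any(water_volume_ml >= vial_volume_ml):
        raise ValidationError("water_volume must be smaller than vial_volume")
    if np.any(headspace_ppb < 0):
        raise ValidationError("headspace_ppb must be >= 0")
    if np.any(pressure_atm <= 0):
        raise ValidationError("pressure must be > 0 atm")

    t_k = np.asarray(equilibration_temp_c, dtype=float) + CELSIUS_OFFSET
    partial_atm = headspace_ppb * 1e-9 * pressure_atm
    headspace_l = (vial_volume_ml - water_volume_ml) / 1000.0
    water_l = water_volume_ml / 1000.0

    mol_headspace = partial_atm * headspace_l / (R_L_ATM_PER_MOL_K * t_k)
    k0 = n2o_solubility(equilibration_temp_c, basis=basis)
    mol_dissolved = k0 * partial_atm * water_l

    mol_per_l = (mol_headspace + mol_dissolved) / water_l
    out = mol_per_l * GRAMS_N_PER_MOL_N2O * 1e6
    return float(out) if out.ndim == 0 else out


def headspace_to_dissolved(sample: GasSample,
                           basis: str = DEFAULT_SOLUBILITY_BASIS) -> float:
    """Dissolved N2O concentration C_obs (ug N/L) of one vial sample."""
    return dissolved_from_headspace(
        sample.headspace_ppb,
        sample.equilibration_temp,
        sample.pressure,
        sample.vial_volume,
        sample.water_volume,
        basis=basis,
    )
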