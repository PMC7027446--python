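"""National stream-network N2O budget.

The national emission estimate treats the low-order (Strahler 1-4)
stream network as a grid of strata, one per stream order x land-use
class, each carrying a water surface area and a gas transfer velocity
summary. The annual emission of a stratum is

    E = 365 * delta * k_N2O * A

with delta the mean excess N2O concentration of the class's survey
records (mg N/L, equivalently g N/m3), k_N2O the class k600 converted to
N2O at the class's mean water temperature (m/day), and A the stratum
water surface area (m2). Class and national totals are plain sums over
strata; the national total converts to CO2-equivalents through the
N2O molar mass (44/28 relative to the N basis) and a global warming
potential of 298.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import gas_physics
from .errors import ConfigurationError, ValidationError

DAYS_PER_YEAR = 365.0
DEFAULT_GWP_N2O = 298.0

DeltaKey = Union[str, tuple]


@dataclass(frozen=True)
class Stratum:
    """One stream-order x land-use cell of the national network."""

    order: int
    landuse_class: str
    area_km2: float
    k600_mean: float  # m/day
    k600_median: float = float("nan")
    k600_p10: float = float("nan")
    k600_p90: float = float("nan")
    length_km: float = float("nan")
    width_m: float = float("nan")

    def __post_init__(self):
        if self.area_km2 < 0:
            raise ValidationError(
                f"stratum order {self.order} {self.landuse_class}: "
                "area must be >= 0"
            )
        if self.k600_mean < 0:
            raise ValidationError(
                f"stratum order {self.order} {self.landuse_class}: "
                "k600_mean must be >= 0"
            )
        if np.isfinite(self.k600_p10) and np.isfinite(self.k600_p90) \
                and self.k600_p10 > self.k600_p90:
            raise ValidationError(
                f"stratum order {self.order} {self.landuse_class}: "
                "k600 p10 exceeds p90"
            )

    @property
    def area_m2(self) -> float:
        return self.area_km2 * 1e6


@dataclass
class FluxEstimate:
    """Per-stratum and aggregate annual N2O emissions.

    ``per_stratum`` has one row per stratum with the inputs used
    (area, k600, temperature, delta) and the resulting emission in
    g N2O-N/year. ``percentiles`` is populated by the Monte Carlo
    propagation (uncertainty module) and maps quantity names to
    (10th, 90th) percentile pairs.
    """

    per_stratum: pd.DataFrame
    class_totals: dict
    national_total: float  # g N2O-N / year
    co2_eq: float  # g CO2-eq / year
    percentiles: Optional[dict] = None
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "class_totals_g_n_per_yr": {k: float(v)
                                        for k, v in self.class_totals.items()},
            "national_total_g_n_per_yr": float(self.national_total),
            "co2_eq_g_per_yr": float(self.co2_eq),
            "per_stratum": self.per_stratum.to_dict(orient="records"),
            "meta": self.meta,
        }
        if self.percentiles is not None:
            out["percentiles"] = {
                k: [float(v[0]), float(v[1])]
                for k, v in self.percentiles.items()
            }
        return out


def strata_from_frame(frame: pd.DataFrame) -> list[Stratum]:
    """Build strata from a table with one row per order x class."""
    required = {"order", "landuse_class", "area_km2", "k600_mean"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"stratum table lacks columns {sorted(missing)}")
    strata = []
    for row in frame.itertuples(index=False):
        strata.append(Stratum(
            order=int(row.order),
            landuse_class=str(row.landuse_class),
            area_km2=float(row.area_km2),
            k600_mean=float(row.k600_mean),
            k600_median=float(getattr(row, "k600_median", float("nan"))),
            k600_p10=float(getattr(row, "k600_p10", float("nan"))),
            k600_p90=float(getattr(row, "k600_p90", float("nan"))),
            length_km=float(getattr(row, "length_km", float("nan"))),
            width_m=float(getattr(row, "width_m", float("nan"))),
        ))
    return strata


def stratum_emission(delta_mg_per_l: float, k_mean_m_per_day: float,
                     area_m2: float) -> float:
    """Annual emission of one stratum, g N2O-N/year.

    E = 365 * delta * k * A, with delta in mg N/L (= g N/m3). Negative
    delta is allowed (net uptake); negative area or k is not.
    """
    if area_m2 < 0:
        raise ValidationError("stream surface area must be >= 0 m2")
    if k_mean_m_per_day < 0:
        raise ValidationError("gas transfer velocity must be >= 0 m/day")
    return DAYS_PER_YEAR * delta_mg_per_l * k_mean_m_per_day * area_m2


def class_mean_delta(records: pd.DataFrame,
                     granularity: str = "class") -> dict:
    """Mean excess concentration (ug N/L) per land-use class.

    ``granularity="class"`` pools every record of the class (the
    default); ``"order"`` returns means keyed by (class, order) for
    classes where order-resolved deltas are wanted.
    """
    if "delta_C" not in records.columns:
        raise ValidationError("records lack delta_C; run classify_records first")
    if granularity == "class":
        return records.groupby("landuse_class")["delta_C"].mean().to_dict()
    if granularity == "order":
        grouped = records.groupby(["landuse_class", "strahler_order"])
        return {(cls, int(order)): mean
                for (cls, order), mean in grouped["delta_C"].mean().items()}
    raise ConfigurationError(
        f"unknown delta granularity {granularity!r}; use 'class' or 'order'"
    )


def class_mean_temperature(records: pd.DataFrame) -> dict:
    """Mean water temperature (C) of each land-use class's records."""
    return records.groupby("landuse_class")["water_temp"].mean().to_dict()


def national_budget(strata: Sequence[Stratum],
                    delta_by_class: Mapping[DeltaKey, float],
                    temperature_by_class: Mapping[str, float],
                    gwp: float = DEFAULT_GWP_N2O,
                    schmidt_set: str = gas_physics.DEFAULT_SCHMIDT_SET,
                    ) -> FluxEstimate:
    """Sum per-stratum annual emissions into class and national totals.

    ``delta_by_class`` maps land-use class (or (class, order) when
    order-resolved deltas are used) to mean excess N2O in ug N/L.
    ``temperature_by_class`` gives the water temperature (C) used for
    the Schmidt-number conversion of each class's k600.
    """
    if not strata:
        raise ValidationError("no strata supplied")
    rows = []
    for stratum in strata:
        key: DeltaKey = stratum.landuse_class
        if key not in delta_by_class:
            key = (stratum.landuse_class, stratum.order)
        if key not in delta_by_class:
            raise ConfigurationError(
                f"no excess-N2O value for stratum class "
                f"{stratum.landuse_class!r} order {stratum.order}"
            )
        if stratum.landuse_class not in temperature_by_class:
            raise ConfigurationError(
                f"no temperature for class {stratum.landuse_class!r}"
            )
        delta_ug_l = float(delta_by_class[key])
        temp_c = float(temperature_by_class[stratum.landuse_class])
        k_n2o = gas_physics.k600_to_kgas(
            stratum.k600_mean, temp_c, coefficient_set=schmidt_set
        )
        emission = stratum_emission(delta_ug_l / 1000.0, k_n2o, stratum.area_m2)
        rows.append({
            "order": stratum.order,
            "landuse_class": stratum.landuse_class,
            "area_km2": stratum.area_km2,
            "k600_mean_m_per_day": stratum.k600_mean,
            "temperature_c": temp_c,
            "k_n2o_m_per_day": k_n2o,
            "delta_ug_n_per_l": delta_ug_l,
            "emission_g_n_per_yr": emission,
        })
    per_stratum = pd.DataFrame(rows)
    class_totals = per_stratum.groupby("landuse_class")["emission_g_n_per_yr"] \
        .sum().to_dict()
    national = float(per_stratum["emission_g_n_per_yr"].sum())
    return FluxEstimate(
        per_stratum=per_stratum,
        class_totals=class_totals,
        national_total=national,
        co2_eq=co2_equivalent(national, gwp),
        meta={
            "gwp": gwp,
            "schmidt_set": schmidt_set,
            "delta_by_class_ug_per_l": {str(k): float(v)
                                        for k, v in delta_by_class.items()},
            "temperature_by_class_c": {str(k): float(v)
                                       for k, v in temperature_by_class.items()},
        },
    )


def budget_from_survey(strata: Sequence[Stratum], records: pd.DataFrame,
                       granularity: str = "class",
                       temperature: Union[str, float] = "class_mean",
                       gwp: float = DEFAULT_GWP_N2O,
                       schmidt_set: str = gas_physics.DEFAULT_SCHMIDT_SET,
                       ) -> FluxEstimate:
    """Convenience wrapper: budget directly from classified records.

    ``temperature`` is either the policy string ``"class_mean"`` (use
    each class's mean water temperature) or a fixed value in C applied
    to every class.
    """
    deltas = class_mean_delta(records, granularity=granularity)
    if temperature == "class_mean":
        temps = class_mean_temperature(records)
    else:
        t = float(temperature)
        temps = {s.landuse_class: t for s in strata}
    return national_budget(strata, deltas, temps, gwp=gwp,
                           schmidt_set=schmidt_set)


def co2_equivalent(emission_g_n_per_yr: float,
                   gwp: float = DEFAULT_GWP_N2O) -> float:
    """Convert g N2O-N/year to g CO2-eq/year.

    N mass -> N2O molecular mass (x44/28), then x GWP.
    """
    if gwp <= 0:
        raise ValidationError("GWP must be > 0")
    return emission_g_n_per_yr \
        * (gas_physics.GRAMS_N2O_PER_MOL / gas_physics.GRAMS_N_PER_MOL_N2O) \
        * gwp


def sector_share(co2_eq_g_per_yr: float, sector_total_g_per_yr: float) -> float:
    """Stream emission as a percentage of a sector's total, 100*x/total."""
    if sector_total_g_per_yr <= 0:
        raise ValidationError("sector total must be > 0")
    return 100.0 * co2_eq_g_per_yr / sector_total_g_per_yr
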