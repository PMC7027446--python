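"""From raw survey rows to the analysis table.

Builds the per-record quantities the budget and the statistical models
consume: the air-equilibrium concentration C_eq, percent saturation,
the excess concentration delta_C = C_obs - C_eq, a meteorological season
label, and the region-level land-use class. Also computes the
N2O-N : NO3-N concentration-ratio statistic (an emission-factor style
summary of how much N2O rides on the nitrate pool in each class).
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import gas_physics
from .errors import ConfigurationError, ValidationError
from .gas_physics import GRAMS_N_PER_MOL_N2O, dissolved_from_headspace, n2o_solubility

logger = logging.getLogger(__name__)

#: Default atmospheric N2O mixing ratio (ppb) used for C_eq.
DEFAULT_X_ATM_PPB = 330.0

#: Region-level land-use classification of the six survey regions:
#: KRY, SES and SRC drain predominantly forested catchments, while
#: SCA, UPP1 and UPP2 drain agricultural ones.
REGION_LANDUSE = {
    "KRY": "forest",
    "SES": "forest",
    "SRC": "forest",
    "SCA": "agricultural",
    "UPP1": "agricultural",
    "UPP2": "agricultural",
}

#: month -> season maps; "meteorological" is the default rule
#: (Dec-Feb winter, Mar-May spring, Jun-Aug summer, Sep-Nov autumn).
SEASON_RULES = {
    "meteorological": {
        12: "winter", 1: "winter", 2: "winter",
        3: "spring", 4: "spring", 5: "spring",
        6: "summer", 7: "summer", 8: "summer",
        9: "autumn", 10: "autumn", 11: "autumn",
    },
}

#: Fraction of TN assumed to be nitrate in forest streams (measured at
#: the one forest region with NO3 data); in agricultural streams TN is
#: itself the NO3 proxy.
DEFAULT_NO3_FRACTION_FOREST = 0.18

HEADSPACE_COLUMNS = (
    "headspace_ppb", "pressure", "vial_volume_ml", "water_volume_ml",
)


def equilibrium_concentration(temp_c, pressure_atm=1.0,
                              x_atm_ppb=DEFAULT_X_ATM_PPB,
                              basis: str = gas_physics.DEFAULT_SOLUBILITY_BASIS):
    """Air-equilibrium dissolved N2O, C_eq, in ug N/L.

    C_eq = K0(T) * x_atm * P, converted to a nitrogen-mass concentration
    (28 g N per mol N2O).
    """
    pressure_atm = np.asarray(pressure_atm, dtype=float)
    x_atm_ppb = np.asarray(x_atm_ppb, dtype=float)
    if np.any(pressure_atm <= 0):
        raise ValidationError("pressure must be > 0 atm")
    if np.any(x_atm_ppb < 0):
        raise ValidationError("atmospheric mixing ratio must be >= 0 ppb")
    k0 = n2o_solubility(temp_c, basis=basis)
    out = np.asarray(k0) * x_atm_ppb * 1e-9 * pressure_atm \
        * GRAMS_N_PER_MOL_N2O * 1e6
    return float(out) if out.ndim == 0 else out


def percent_saturation(c_obs, c_eq):
    """Percent saturation, 100 * C_obs / C_eq.

    Values above 100 indicate supersaturation: the stream is a source of
    N2O to the atmosphere.
    """
    c_obs = np.asarray(c_obs, dtype=float)
    c_eq = np.asarray(c_eq, dtype=float)
    if np.any(c_eq <= 0):
        raise ValidationError("C_eq must be > 0 to compute percent saturation")
    if np.any(c_obs < 0):
        raise ValidationError("C_obs must be >= 0")
    out = 100.0 * c_obs / c_eq
    return float(out) if out.ndim == 0 else out


def season_of(dates, season_rule: str = "meteorological") -> pd.Series:
    """Season label for each date under the configured month rule."""
    try:
        rule = SEASON_RULES[season_rule]
    except KeyError:
        raise ConfigurationError(
            f"unknown season rule {season_rule!r}; "
            f"expected one of {sorted(SEASON_RULES)}"
        ) from None
    months = pd.to_datetime(dates).dt.month if isinstance(dates, pd.Series) \
        else pd.to_datetime(pd.Series(dates)).dt.month
    return months.map(rule)


def convert_headspace(samples: pd.DataFrame,
                      basis: str = gas_physics.DEFAULT_SOLUBILITY_BASIS,
                      ) -> pd.DataFrame:
    """Add a C_obs column computed from the headspace-vial columns.

    The equilibration temperature defaults to the stream water
    temperature when no ``equilibration_temp`` column is present.
    """
    missing = [c for c in HEADSPACE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(
            f"headspace conversion needs columns {missing} (absent)"
        )
    out = samples.copy()
    equil_t = out.get("equilibration_temp", out["water_temp"])
    out["C_obs"] = dissolved_from_headspace(
        out["headspace_ppb"].to_numpy(),
        np.asarray(equil_t, dtype=float),
        out["pressure"].to_numpy(),
        out["vial_volume_ml"].to_numpy(),
        out["water_volume_ml"].to_numpy(),
        basis=basis,
    )
    return out


def classify_records(samples: pd.DataFrame,
                     region_landuse: Optional[Mapping[str, str]] = None,
                     season_rule: str = "meteorological",
                     x_atm_ppb: float = DEFAULT_X_ATM_PPB,
                     basis: str = gas_physics.DEFAULT_SOLUBILITY_BASIS,
                     ) -> pd.DataFrame:
    """Build the analysis table from per-sample inputs.

    Requires ``C_obs`` (run :func:`convert_headspace` first when only
    headspace fields are present). Adds ``landuse_class`` (by region),
    ``season`` (from the date), ``C_eq``, ``pct_sat``, ``delta_C`` and a
    ``supersaturated`` flag. Undersaturated records are kept; they carry
    negative excess concentrations (net uptake).
    """
    if region_landuse is None:
        region_landuse = REGION_LANDUSE
    if "C_obs" not in samples.columns:
        raise ValidationError(
            "classify_records requires a C_obs column; convert headspace "
            "measurements first"
        )
    records = samples.copy()

    regions = records["region_id"].astype(str)
    unmapped = sorted(set(regions) - set(region_landuse))
    if unmapped:
        raise ConfigurationError(
            f"no land-use class configured for region(s) {unmapped}"
        )
    records["landuse_class"] = regions.map(region_landuse)
    records["season"] = season_of(records["date"], season_rule)

    pressure = records["pressure"].to_numpy() if "pressure" in records \
        else np.ones(len(records))
    records["C_eq"] = equilibrium_concentration(
        records["water_temp"].to_numpy(), pressure, x_atm_ppb, basis=basis
    )
    records["pct_sat"] = percent_saturation(
        records["C_obs"].to_numpy(), records["C_eq"].to_numpy()
    )
    records["delta_C"] = records["C_obs"] - records["C_eq"]
    records["supersaturated"] = records["pct_sat"] > 100.0

    n_under = int((~records["supersaturated"]).sum())
    logger.info(
        "classified %d records (%d undersaturated, kept with negative delta_C)",
        len(records), n_under,
    )
    return records


def emission_factor_ratio(records: pd.DataFrame,
                          no3_fraction_forest: float = DEFAULT_NO3_FRACTION_FOREST,
                          ) -> pd.DataFrame:
    """Per-class N2O-N : NO3-N ratio summary (median and 10th-90th pct).

    NO3-N is approximated from TN: in agricultural streams nitrate makes
    up most of TN, so TN is used directly; in forest streams a fixed
    nitrate fraction of TN is applied. Records with missing or
    non-positive NO3-N are excluded (the count is logged and reported).
    """
    if not 0 < no3_fraction_forest <= 1:
        raise ValidationError("no3_fraction_forest must be in (0, 1]")
    required = {"landuse_class", "C_obs", "TN"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"emission_factor_ratio needs columns {sorted(missing)}")

    frame = records.copy()
    frac = np.where(frame["landuse_class"] == "forest", no3_fraction_forest, 1.0)
    frame["no3_n"] = frame["TN"] * frac

    rows = []
    for cls, grp in frame.groupby("landuse_class", sort=True):
        usable = grp[(grp["no3_n"] > 0) & grp["no3_n"].notna()
                     & grp["C_obs"].notna()]
        n_excluded = len(grp) - len(usable)
        if n_excluded:
            logger.info("emission_factor_ratio: excluded %d %s records "
                        "with zero/missing NO3-N", n_excluded, cls)
        ratio = usable["C_obs"] / usable["no3_n"]
        rows.append({
            "landuse_class": cls,
            "n_used": len(usable),
            "n_excluded": n_excluded,
            "median": ratio.median(),
            "p10": ratio.quantile(0.10),
            "p90": ratio.quantile(0.90),
        })
    return pd.DataFrame(rows).set_index("landuse_class")
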