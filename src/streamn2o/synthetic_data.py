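"""Seeded generator of survey datasets with the structure the analysis assumes.

The generator emulates a six-region Swedish stream survey (three forest
regions: KRY, SES, SRC; three agricultural: SCA, UPP1, UPP2; ~1,000
site-visits in total). Each record is produced by a known data-generating
model so that every downstream stage — headspace conversion, saturation,
mixed-effects fitting, upscaling — can be tested against recorded truth:

1. covariates (TN, DOC, pH, land-use percentages, Strahler order, a
   seasonal water-temperature curve, barometric pressure) are drawn from
   region-specific distributions;
2. ln(%sat) is computed from a linear model (intercept + slopes on the
   covariates + season and order multipliers + region effect + residual
   noise);
3. the dissolved concentration is back-computed from %sat through the
   air-equilibrium concentration at the drawn temperature, and the
   headspace-vial partition is forward-simulated so both ingestion paths
   (raw vials or pre-computed concentrations) are exercised.

With ``calibrate_regions=True`` (the shipped default) the region effects
are moment-matched so each region's expected dissolved-N2O mean equals
its configured target; otherwise they are drawn from a normal
distribution with the truth's region standard deviation. Every generated
dataset is accompanied by a truth sidecar holding all generator
parameters and the realised region effects, which is what parameter-
recovery tests read.

The module also ships the national stream-network stratum table
(stream order x land-use surface areas and k600 summaries for the
non-alpine network) used by the upscaling stage.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gas_physics import (
    CELSIUS_OFFSET,
    GRAMS_N_PER_MOL_N2O,
    R_L_ATM_PER_MOL_K,
    n2o_solubility,
)
from .survey_processing import DEFAULT_X_ATM_PPB, SEASON_RULES


@dataclass(frozen=True)
class RegionSpec:
    """Distributional description of one survey region.

    Concentration-like quantities (N2O target mean, TN, DOC) are
    lognormal on the original scale; pH is truncated normal; water
    temperature follows a seasonal cosine (peak in July) with noise.
    ``months`` are the calendar months actually visited and ``n_obs``
    the total number of site-visits to emit.
    """

    region_id: str
    landuse_class: str
    n_sites: int
    n_obs: int
    months: tuple[int, ...]
    order_probs: tuple[float, ...]  # P(order 1), P(order 2), ...
    n2o_mean: float  # ug N/L, calibration target for the region mean
    tn_mean: float  # ug N/L
    tn_sd: float
    doc_mean: float  # mg/L
    doc_sd: float
    ph_mean: float
    ph_sd: float
    temp_mean: float  # C, annual mean of the seasonal curve
    temp_amplitude: float  # C, half peak-to-trough
    temp_sd: float = 1.5
    agriculture_range: tuple[float, float] = (0.0, 5.0)  # % of subcatchment
    forest_range: tuple[float, float] = (50.0, 100.0)
    wetland_range: tuple[float, float] = (0.0, 10.0)
    year: int = 2016
    dropout_prob: float = 0.0  # visit-level missingness (droughts); default off

    def __post_init__(self):
        for name in ("tn_sd", "doc_sd", "ph_sd", "temp_sd", "n2o_mean",
                     "tn_mean", "doc_mean"):
            if getattr(self, name) < 0 or not math.isfinite(getattr(self, name)):
                raise ValidationError(
                    f"region {self.region_id}: {name} must be finite and >= 0"
                )
        if self.n_sites < 1 or self.n_obs < 1:
            raise ValidationError(
                f"region {self.region_id}: need at least one site and one visit"
            )
        if not math.isclose(sum(self.order_probs), 1.0, rel_tol=1e-9):
            raise ValidationError(
                f"region {self.region_id}: order probabilities must sum to 1"
            )
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValidationError(
                f"region {self.region_id}: dropout_prob must be in [0, 1)"
            )


@dataclass(frozen=True)
class GeneratorTruth:
    """The data-generating model for ln(%sat), recorded with every dataset.

    Slope defaults are the saturation-model coefficients the recovery
    tests target (TN 0.00023 per ug N/L, pH -0.17 per unit, intercept
    6.44 on the ln-percent scale); season and order multipliers scale
    %sat multiplicatively per land-use class.
    """

    intercept: float = 6.44
    tn_slope: float = 0.00023
    ph_slope: float = -0.17
    agriculture_slope: float = 0.003
    wetland_slope: float = -0.0005
    doc_slope: float = -0.003
    temp_slope: float = -0.0001
    region_sd: float = 0.4
    residual_sd: float = 0.6
    season_multipliers: dict = field(default_factory=lambda: {
        # relative %sat by season, from the survey's seasonal contrasts:
        # forest peaks in autumn, agricultural streams in winter.
        "forest": {"winter": 0.70, "spring": 0.86, "summer": 0.72,
                   "autumn": 1.72},
        "agricultural": {"winter": 1.69, "spring": 0.67, "summer": 0.71,
                         "autumn": 0.94},
    })
    order_multipliers: dict = field(default_factory=lambda: {
        # relative %sat by Strahler order: decreasing in forest,
        # increasing in agricultural streams.
        "forest": {1: 1.27, 2: 1.02, 3: 0.90, 4: 0.81, 5: 0.81},
        "agricultural": {1: 0.92, 2: 0.82, 3: 0.92, 4: 1.34, 5: 1.34},
    })
    # standard vial geometry used when forward-simulating the headspace
    vial_volume_ml: float = 22.5
    water_volume_ml: float = 10.0

    def __post_init__(self):
        if self.region_sd < 0 or self.residual_sd < 0:
            raise ValidationError("truth standard deviations must be >= 0")

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["season_multipliers"] = {
            cls: dict(v) for cls, v in self.season_multipliers.items()
        }
        out["order_multipliers"] = {
            cls: {str(k): v for k, v in ords.items()}
            for cls, ords in self.order_multipliers.items()
        }
        return out


def default_region_specs() -> list[RegionSpec]:
    """The six shipped region specifications (the survey calibration).

    Means, spreads, sample sizes, months and land-use mixes follow the
    published per-region survey summaries the package is calibrated to.
    """
    return [
        RegionSpec("KRY", "forest", n_sites=15, n_obs=420,
                   months=tuple(range(1, 13)),
                   order_probs=(0.50, 0.25, 0.15, 0.10),
                   n2o_mean=1.3, tn_mean=410, tn_sd=250,
                   doc_mean=17.5, doc_sd=7.1, ph_mean=5.4, ph_sd=0.8,
                   temp_mean=4.5, temp_amplitude=6.0,
                   agriculture_range=(0, 4), forest_range=(59, 100),
                   wetland_range=(0, 40), year=2004),
        RegionSpec("SES", "forest", n_sites=103, n_obs=227,
                   months=(3, 4, 8, 9, 11, 12),
                   order_probs=(1.0,),
                   n2o_mean=1.6, tn_mean=1020, tn_sd=680,
                   doc_mean=27.8, doc_sd=16.0, ph_mean=5.4, ph_sd=0.9,
                   temp_mean=8.0, temp_amplitude=7.5,
                   agriculture_range=(0, 5), forest_range=(48, 100),
                   wetland_range=(0, 44), year=2016),
        RegionSpec("SRC", "forest", n_sites=17, n_obs=41,
                   months=(3, 4, 5, 6, 7),
                   order_probs=(0.7, 0.3),
                   n2o_mean=0.8, tn_mean=690, tn_sd=160,
                   doc_mean=25.5, doc_sd=7.4, ph_mean=6.1, ph_sd=0.7,
                   temp_mean=8.5, temp_amplitude=7.0,
                   agriculture_range=(0, 10), forest_range=(70, 100),
                   wetland_range=(0, 4), year=2014),
        RegionSpec("SCA", "agricultural", n_sites=18, n_obs=72,
                   months=(5, 6),
                   order_probs=(0.5, 0.3, 0.2),
                   n2o_mean=0.9, tn_mean=3300, tn_sd=2940,
                   doc_mean=8.1, doc_sd=6.5, ph_mean=8.0, ph_sd=0.3,
                   temp_mean=9.5, temp_amplitude=7.0,
                   agriculture_range=(9, 97), forest_range=(0, 74),
                   wetland_range=(0, 7), year=2016),
        RegionSpec("UPP1", "agricultural", n_sites=9, n_obs=130,
                   months=tuple(range(1, 13)),
                   order_probs=(0.40, 0.35, 0.25),
                   n2o_mean=2.0, tn_mean=1620, tn_sd=1490,
                   doc_mean=8.6, doc_sd=3.6, ph_mean=7.8, ph_sd=0.4,
                   temp_mean=7.5, temp_amplitude=7.5,
                   agriculture_range=(0, 63), forest_range=(25, 84),
                   wetland_range=(0, 16), year=2017),
        RegionSpec("UPP2", "agricultural", n_sites=10, n_obs=96,
                   months=(6, 7, 8, 9, 10, 11),
                   order_probs=(0.30, 0.25, 0.20, 0.15, 0.10),
                   n2o_mean=1.4, tn_mean=1050, tn_sd=1200,
                   doc_mean=12.4, doc_sd=3.4, ph_mean=7.8, ph_sd=0.2,
                   temp_mean=8.0, temp_amplitude=7.5,
                   agriculture_range=(23, 79), forest_range=(8, 93),
                   wetland_range=(0, 2), year=2017),
    ]


def _lognormal(rng: np.random.Generator, mean: float, sd: float, n: int,
               floor: float = 0.0) -> np.ndarray:
    """Lognormal draws parameterised by original-scale mean and sd."""
    if mean <= 0:
        raise ValidationError("lognormal mean must be > 0")
    if sd == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    draws = rng.lognormal(mu, math.sqrt(sigma2), n)
    return np.maximum(draws, floor)


def _seasonal_temperature(rng: np.random.Generator, months: np.ndarray,
                          spec: RegionSpec) -> np.ndarray:
    """Cosine annual cycle peaking in July, clipped to flowing water."""
    seasonal = spec.temp_mean + spec.temp_amplitude * np.cos(
        2.0 * np.pi * (months - 7) / 12.0
    )
    temps = seasonal + rng.normal(0.0, spec.temp_sd, len(months))
    return np.clip(temps, 0.2, 26.0)


def _headspace_from_dissolved(c_obs_ug_l: np.ndarray, temp_c: np.ndarray,
                              pressure_atm: np.ndarray, vial_ml: float,
                              water_ml: float) -> np.ndarray:
    """Forward vial partition: the GC mixing ratio (ppb) a vial would read."""
    water_l = water_ml / 1000.0
    head_l = (vial_ml - water_ml) / 1000.0
    mol_total = c_obs_ug_l * 1e-6 / GRAMS_N_PER_MOL_N2O * water_l
    t_k = temp_c + CELSIUS_OFFSET
    # mol_total = p * (head_l/(R T) + K0 * water_l), p = x * 1e-9 * P
    denom = head_l / (R_L_ATM_PER_MOL_K * t_k) \
        + n2o_solubility(temp_c) * water_l
    partial_atm = mol_total / denom
    return partial_atm / (1e-9 * pressure_atm)


def generate_survey(specs: Optional[Sequence[RegionSpec]] = None,
                    truth: Optional[GeneratorTruth] = None,
                    seed: int = 0,
                    calibrate_regions: bool = True,
                    x_atm_ppb: float = DEFAULT_X_ATM_PPB,
                    season_rule: str = "meteorological",
                    out_csv=None, sidecar=None,
                    ) -> tuple[pd.DataFrame, dict]:
    """Generate a survey table and its truth sidecar.

    Returns ``(frame, truth_sidecar)``. The frame carries both the raw
    headspace-vial fields and the derived ``C_obs`` so either ingestion
    path of the pipeline can be exercised; the sidecar records every
    parameter of the generating model, including the realised region
    effects, and is the only thing recovery tests may consult.
    """
    if specs is None:
        specs = default_region_specs()
    if truth is None:
        truth = GeneratorTruth()
    season_map = SEASON_RULES[season_rule]
    rng = np.random.default_rng(seed)

    frames = []
    region_effects: dict[str, float] = {}
    for spec in specs:
        n = spec.n_obs
        # -- sites: Strahler order and land-use mix are site properties
        orders_by_site = rng.choice(
            np.arange(1, len(spec.order_probs) + 1), size=spec.n_sites,
            p=spec.order_probs,
        )
        ag_by_site = rng.uniform(*spec.agriculture_range, spec.n_sites)
        wet_by_site = rng.uniform(*spec.wetland_range, spec.n_sites)
        forest_by_site = np.minimum(
            rng.uniform(*spec.forest_range, spec.n_sites),
            100.0 - ag_by_site - wet_by_site,
        )

        # -- visits: cycle sites through the sampled months
        site_idx = np.arange(n) % spec.n_sites
        months = np.asarray(spec.months)[
            (np.arange(n) // spec.n_sites) % len(spec.months)
        ]
        days = rng.integers(1, 29, n)
        if spec.dropout_prob > 0.0:
            keep = rng.random(n) >= spec.dropout_prob
            site_idx, months, days = site_idx[keep], months[keep], days[keep]
            n = len(site_idx)

        temps = _seasonal_temperature(rng, months, spec)
        pressure = np.clip(rng.normal(1.0, 0.012, n), 0.94, 1.05)
        tn = _lognormal(rng, spec.tn_mean, spec.tn_sd, n, floor=5.0)
        doc = _lognormal(rng, spec.doc_mean, spec.doc_sd, n, floor=0.5)
        ph = np.clip(rng.normal(spec.ph_mean, spec.ph_sd, n), 3.5, 9.5)

        seasons = np.array([season_map[m] for m in months])
        season_mult = np.array([
            truth.season_multipliers[spec.landuse_class][s] for s in seasons
        ])
        order = orders_by_site[site_idx]
        order_mult = np.array([
            truth.order_multipliers[spec.landuse_class][o] for o in order
        ])

        linear = (
            truth.intercept
            + truth.tn_slope * tn
            + truth.ph_slope * ph
            + truth.agriculture_slope * ag_by_site[site_idx]
            + truth.wetland_slope * wet_by_site[site_idx]
            + truth.doc_slope * doc
            + truth.temp_slope * temps
            + np.log(season_mult) + np.log(order_mult)
        )
        c_eq = n2o_solubility(temps) * x_atm_ppb * 1e-9 * pressure \
            * GRAMS_N_PER_MOL_N2O * 1e6

        if calibrate_regions:
            # moment-match the region effect so E[C_obs] over the residual
            # distribution equals the region's configured N2O mean,
            # conditional on the drawn covariates
            raw_mean = float(np.mean(c_eq / 100.0 * np.exp(linear)))
            b_region = math.log(spec.n2o_mean) \
                - truth.residual_sd ** 2 / 2.0 - math.log(raw_mean)
        else:
            b_region = float(rng.normal(0.0, truth.region_sd))
        region_effects[spec.region_id] = b_region

        ln_sat = linear + b_region + rng.normal(0.0, truth.residual_sd, n)
        pct_sat = np.exp(ln_sat)
        c_obs = c_eq * pct_sat / 100.0
        headspace_ppb = _headspace_from_dissolved(
            c_obs, temps, pressure, truth.vial_volume_ml, truth.water_volume_ml
        )

        frames.append(pd.DataFrame({
            "region_id": spec.region_id,
            "site_id": [f"{spec.region_id}-{i + 1:03d}" for i in site_idx],
            "date": [f"{spec.year}-{m:02d}-{d:02d}"
                     for m, d in zip(months, days)],
            "strahler_order": order,
            "pct_agriculture": np.round(ag_by_site[site_idx], 2),
            "pct_forest": np.round(forest_by_site[site_idx], 2),
            "pct_wetland": np.round(wet_by_site[site_idx], 2),
            "water_temp": temps,
            "equilibration_temp": temps,
            "pressure": pressure,
            "vial_volume_ml": truth.vial_volume_ml,
            "water_volume_ml": truth.water_volume_ml,
            "headspace_ppb": headspace_ppb,
            "C_obs": c_obs,
            "TN": tn,
            "DOC": doc,
            "pH": ph,
        }))

    frame = pd.concat(frames, ignore_index=True)
    frame.insert(0, "sample_id",
                 [f"S{i + 1:05d}" for i in range(len(frame))])

    sidecar_dict = {
        "seed": int(seed),
        "x_atm_ppb": float(x_atm_ppb),
        "season_rule": season_rule,
        "calibrate_regions": bool(calibrate_regions),
        "truth": truth.as_dict(),
        "region_effects": region_effects,
        "region_targets": {s.region_id: s.n2o_mean for s in specs},
        "region_landuse": {s.region_id: s.landuse_class for s in specs},
        "n_records": int(len(frame)),
    }
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    if sidecar is not None:
        with open(sidecar, "w") as fh:
            json.dump(sidecar_dict, fh, indent=2, sort_keys=True)
    return frame, sidecar_dict


# ---------------------------------------------------------------------------
# National stream-network stratum table (non-alpine network, orders 1-4).
# Columns: order, land-use class, class water surface area (km2), k600
# summaries (m/day), plus the order-level network totals for provenance.
# ---------------------------------------------------------------------------

_STRATA_ROWS = [
    # order, class, area_km2, k600_mean, k600_median, k600_p10, k600_p90,
    # length_km (whole order), width_m, area_total_km2 (whole order)
    (1, "forest", 125.0, 9.3, 4.5, 0.3, 21.7, 228993.0, 0.7, 164.0),
    (1, "agricultural", 26.0, 3.7, 1.7, 0.1, 8.3, 228993.0, 0.7, 164.0),
    (2, "forest", 122.0, 9.8, 5.3, 0.4, 22.1, 101521.0, 1.6, 165.0),
    (2, "agricultural", 31.0, 4.4, 2.4, 0.2, 9.6, 101521.0, 1.6, 165.0),
    (3, "forest", 126.0, 10.5, 6.0, 0.6, 23.9, 47650.0, 3.7, 175.0),
    (3, "agricultural", 39.0, 5.3, 3.3, 0.4, 12.1, 47650.0, 3.7, 175.0),
    (4, "forest", 138.0, 10.3, 6.4, 0.6, 23.2, 23244.0, 8.4, 194.0),
    (4, "agricultural", 48.0, 6.1, 3.7, 0.5, 13.9, 23244.0, 8.4, 194.0),
]


def generate_strata(out_csv=None) -> pd.DataFrame:
    """The packaged national stratum table (order x land-use, km2, m/day)."""
    frame = pd.DataFrame(_STRATA_ROWS, columns=[
        "order", "landuse_class", "area_km2", "k600_mean", "k600_median",
        "k600_p10", "k600_p90", "length_km", "width_m", "area_total_km2",
    ])
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return frame
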