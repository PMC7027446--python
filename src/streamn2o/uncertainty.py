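"""Monte Carlo propagation of budget uncertainty.

Two quantities carry the reported spread and are varied: the class mean
excess concentration (bootstrap over that class's survey records) and
each stratum's gas transfer velocity (a lognormal matched to the
stratum's published mean and 10th/90th percentiles). Stream surface
areas and the Schmidt temperature are held fixed.

The simulation is organised as an outer loop of *repetitions* around an
inner loop of *iterations*: each repetition draws ``n_iterations``
budgets and records their 10th/90th percentiles; the reported interval
is the mean of those per-repetition percentiles across repetitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import gas_physics
from .errors import ValidationError
from .upscaling import (
    DAYS_PER_YEAR,
    DEFAULT_GWP_N2O,
    FluxEstimate,
    Stratum,
    budget_from_survey,
    class_mean_temperature,
    co2_equivalent,
)

#: z-score of the 90th percentile, used for quantile matching.
_Z90 = stats.norm.ppf(0.90)


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings.

    The full-size simulation is 10,000 repetitions x 10,000 iterations;
    scaled-down counts (e.g. 50 x 2,000) give stable percentiles for
    testing. ``seed`` makes the whole simulation reproducible.
    """

    n_iterations: int = 10_000
    n_repetitions: int = 10_000
    seed: int = 0
    k_distribution: str = "lognormal-matched"
    delta_resampling: str = "bootstrap"

    def __post_init__(self):
        if self.n_iterations < 1 or self.n_repetitions < 1:
            raise ValidationError("iteration and repetition counts must be >= 1")
        if self.k_distribution not in ("lognormal-matched",
                                       "empirical-percentile"):
            raise ValidationError(
                f"unknown k_distribution {self.k_distribution!r}"
            )
        if self.delta_resampling not in ("bootstrap", "parametric-lognormal"):
            raise ValidationError(
                f"unknown delta_resampling {self.delta_resampling!r}"
            )


def lognormal_from_summary(mean: float, p10: float, p90: float
                           ) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and p10-p90 spread.

    sigma comes from the decile ratio (ln(p90/p10) = 2 z90 sigma) and mu
    from the mean (mu = ln(mean) - sigma^2/2), so draws reproduce the
    published mean exactly and the published relative spread. A
    degenerate summary (p10 == p90) yields sigma = 0; p10 > p90 is
    rejected.
    """
    if mean <= 0:
        raise ValidationError("k600 mean must be > 0 to fit a lognormal")
    if p10 > p90:
        raise ValidationError(f"k600 p10 ({p10}) exceeds p90 ({p90})")
    if p10 <= 0 or p90 <= 0:
        raise ValidationError("k600 percentiles must be > 0")
    sigma = math.log(p90 / p10) / (2.0 * _Z90)
    mu = math.log(mean) - sigma * sigma / 2.0
    return mu, sigma


def _delta_draws(rng: np.random.Generator, deltas: np.ndarray,
                 n: int, how: str) -> np.ndarray:
    """n draws of the class mean excess concentration (ug N/L)."""
    if how == "bootstrap":
        idx = rng.integers(0, len(deltas), size=(n, len(deltas)))
        return deltas[idx].mean(axis=1)
    # parametric alternative: lognormal on the positive shifted scale is
    # fragile for near-zero means, so the sampling distribution of the
    # mean is approximated as normal (CLT at survey sample sizes)
    se = deltas.std(ddof=1) / math.sqrt(len(deltas))
    return rng.normal(deltas.mean(), se, n)


def mc_budget(strata: Sequence[Stratum], records: pd.DataFrame,
              cfg: MCConfig,
              temperature: Union[str, float] = "class_mean",
              gwp: float = DEFAULT_GWP_N2O,
              schmidt_set: str = gas_physics.DEFAULT_SCHMIDT_SET,
              ) -> FluxEstimate:
    """Budget point estimate with Monte Carlo percentile intervals.

    Returns the deterministic :func:`budget_from_survey` estimate with
    ``percentiles`` filled in: for the national total and each class
    total, the mean over repetitions of the per-repetition 10th and 90th
    percentiles.
    """
    classes = sorted({s.landuse_class for s in strata})
    for cls in classes:
        if not len(records[records["landuse_class"] == cls]):
            raise ValidationError(f"no survey records for class {cls!r}")
    point = budget_from_survey(strata, records, temperature=temperature,
                               gwp=gwp, schmidt_set=schmidt_set)

    if temperature == "class_mean":
        temps = class_mean_temperature(records)
    else:
        temps = {cls: float(temperature) for cls in classes}
    sc_factor = {
        cls: (gas_physics.schmidt_number(temps[cls], coefficient_set=schmidt_set)
              / gas_physics.SCHMIDT_REFERENCE) ** -0.5
        for cls in classes
    }
    deltas_by_class = {
        cls: records.loc[records["landuse_class"] == cls, "delta_C"]
        .to_numpy(dtype=float)
        for cls in classes
    }
    k_params = []
    for s in strata:
        if cfg.k_distribution == "lognormal-matched" \
                and np.isfinite(s.k600_p10) and np.isfinite(s.k600_p90) \
                and s.k600_p10 != s.k600_p90:
            k_params.append(("lognormal",
                             *lognormal_from_summary(s.k600_mean, s.k600_p10,
                                                     s.k600_p90)))
        elif cfg.k_distribution == "empirical-percentile" \
                and np.isfinite(s.k600_p10) and np.isfinite(s.k600_p90):
            k_params.append(("empirical", s.k600_p10, s.k600_median,
                             s.k600_p90))
        else:
            k_params.append(("point", s.k600_mean, 0.0))

    rng = np.random.default_rng(cfg.seed)
    n_iter = cfg.n_iterations
    rep_pcts = {"national": []}
    rep_pcts.update({cls: [] for cls in classes})
    all_means = []

    for _ in range(cfg.n_repetitions):
        delta_draw = {
            cls: _delta_draws(rng, deltas_by_class[cls], n_iter,
                              cfg.delta_resampling)
            for cls in classes
        }
        class_totals = {cls: np.zeros(n_iter) for cls in classes}
        for s, params in zip(strata, k_params):
            kind = params[0]
            if kind == "lognormal":
                k600 = rng.lognormal(params[1], params[2], n_iter)
            elif kind == "empirical":
                # resample the published deciles/median (2:6:2 weights)
                k600 = rng.choice(np.asarray(params[1:]), size=n_iter,
                                  p=(0.2, 0.6, 0.2))
            else:
                k600 = np.full(n_iter, params[1])
            cls = s.landuse_class
            class_totals[cls] += (
                DAYS_PER_YEAR * delta_draw[cls] / 1000.0
                * k600 * sc_factor[cls] * s.area_m2
            )
        national = sum(class_totals.values())
        rep_pcts["national"].append(np.percentile(national, (10.0, 90.0)))
        for cls in classes:
            rep_pcts[cls].append(np.percentile(class_totals[cls], (10.0, 90.0)))
        all_means.append(national.mean())

    reps = cfg.n_repetitions
    rep_arrays = {name: np.asarray(vals) for name, vals in rep_pcts.items()}
    point.percentiles = {
        name: tuple(arr.mean(axis=0)) for name, arr in rep_arrays.items()
    }
    # Monte Carlo standard error of each reported percentile, over repetitions
    percentile_se = {
        name: tuple(arr.std(axis=0, ddof=1) / math.sqrt(reps)
                    if reps > 1 else (0.0, 0.0))
        for name, arr in rep_arrays.items()
    }
    point.percentiles["national_co2_eq"] = tuple(
        co2_equivalent(v, gwp) for v in point.percentiles["national"]
    )
    point.meta["mc"] = {
        "n_iterations": n_iter,
        "n_repetitions": reps,
        "seed": cfg.seed,
        "k_distribution": cfg.k_distribution,
        "delta_resampling": cfg.delta_resampling,
        "mean_of_iteration_means_g_n_per_yr": float(np.mean(all_means)),
        "percentile_se": {name: [float(v[0]), float(v[1])]
                          for name, v in percentile_se.items()},
    }
    return point
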