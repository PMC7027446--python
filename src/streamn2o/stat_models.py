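"""Mixed-effects models of N2O percent saturation.

Replicates the survey's statistical toolkit: a random-intercept
(region) linear mixed model of ln(%sat) against water-chemistry and
land-use covariates fitted by REML, likelihood-ratio comparison against
the null model, Tukey-adjusted pairwise group contrasts, and variance
inflation factors for collinearity screening.

Percent saturation is always modelled on the natural-log scale; degrees
of freedom are reported as n minus the number of fixed-effect
parameters (conventions differ across software — estimates, standard
errors and signs are the comparable quantities, not df).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .errors import ValidationError

logger = logging.getLogger(__name__)

ALPHA = 0.05

DEFAULT_PREDICTORS = (
    "TN", "DOC", "pH", "pct_agriculture", "pct_wetland", "water_temp",
)

#: column behind each grouping keyword of compare_groups
GROUPING_COLUMNS = {
    "landuse": "landuse_class",
    "season": "season",
    "order": "strahler_order",
}


@dataclass
class ModelFit:
    """Coefficient table and fit summary of one mixed model."""

    coefficients: pd.DataFrame  # term, estimate, se, ci_low, ci_high, df, t, p
    random_effect_variance: float
    residual_variance: float
    n_observations: int
    n_dropped: int
    loglik: float
    null_comparison_p: float
    singular: bool = False
    contrasts: Optional[pd.DataFrame] = None
    omnibus_p: Optional[float] = None
    meta: dict = field(default_factory=dict)


def _listwise(records: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    data = records[list(columns)].dropna()
    n_dropped = len(records) - len(data)
    if n_dropped:
        logger.info("listwise deletion dropped %d of %d records",
                    n_dropped, len(records))
    return data


def _mixedlm_fit(endog, exog, groups, reml=True):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=groups)
        result = model.fit(reml=reml)
        if not np.isfinite(result.llf):
            result = model.fit(reml=reml, method="powell")
        return result


def _lrt_vs_null(endog, exog, groups) -> float:
    """Likelihood-ratio p-value of the fixed effects, ML fits."""
    full = _mixedlm_fit(endog, exog, groups, reml=False)
    null = _mixedlm_fit(endog, exog[:, :1], groups, reml=False)
    stat = 2.0 * (full.llf - null.llf)
    df = exog.shape[1] - 1
    return float(stats.chi2.sf(max(stat, 0.0), df))


def fit_saturation_model(records: pd.DataFrame,
                         predictors: Sequence[str] = DEFAULT_PREDICTORS,
                         response: str = "pct_sat",
                         group: str = "region_id",
                         vif_threshold: float = 10.0) -> ModelFit:
    """REML random-intercept model of ln(%sat) on continuous covariates.

    Records with any missing value among response, predictors or group
    are dropped listwise (count logged and reported). Predictors are
    screened with variance inflation factors first; terms at or above
    ``vif_threshold`` raise, since the model's coefficients would not be
    interpretable. A zero region variance (singular fit) is flagged,
    not fatal.
    """
    cols = [response, group, *predictors]
    data = _listwise(records, cols)
    n_groups = data[group].nunique()
    if n_groups < 2:
        raise ValidationError(
            f"need >= 2 groups in {group!r} for a mixed model, got {n_groups}"
        )

    vif = vif_screen(data, predictors)
    flagged = vif[vif["vif"] >= vif_threshold]
    if len(flagged):
        raise ValidationError(
            "predictors fail the collinearity screen (VIF >= "
            f"{vif_threshold}): {list(flagged.index)}"
        )

    endog = np.log(data[response].to_numpy(dtype=float))
    exog = sm.add_constant(data[list(predictors)].to_numpy(dtype=float))
    groups = data[group].to_numpy()

    result = _mixedlm_fit(endog, exog, groups, reml=True)
    k = exog.shape[1]
    terms = ["intercept", *predictors]
    params = np.asarray(result.fe_params)
    se = np.asarray(result.bse_fe)
    zcrit = stats.norm.ppf(1 - ALPHA / 2)
    tvals = params / se
    df_resid = len(endog) - k
    coef = pd.DataFrame({
        "term": terms,
        "estimate": params,
        "se": se,
        "ci_low": params - zcrit * se,
        "ci_high": params + zcrit * se,
        "df": df_resid,
        "t": tvals,
        "p": 2 * stats.norm.sf(np.abs(tvals)),
    })

    re_var = float(np.asarray(result.cov_re).ravel()[0]) \
        if result.cov_re.size else 0.0
    singular = re_var <= 1e-10
    if singular:
        warnings.warn("singular fit: region variance is (near) zero",
                      stacklevel=2)

    return ModelFit(
        coefficients=coef,
        random_effect_variance=re_var,
        residual_variance=float(result.scale),
        n_observations=len(endog),
        n_dropped=len(records) - len(data),
        loglik=float(result.llf),
        null_comparison_p=_lrt_vs_null(endog, exog, groups),
        singular=singular,
        meta={"vif": vif["vif"].to_dict(), "reml": True,
              "response_transform": "ln"},
    )


def _tukey_contrasts(levels, params, cov, df_resid) -> pd.DataFrame:
    """All pairwise contrasts with studentized-range adjusted p-values.

    ``params``/``cov`` are the fixed-effect estimates for (intercept,
    level_2, ..., level_k) under treatment coding, so level means are
    intercept (+ dummy coefficient) and contrast variances come from the
    coefficient covariance.
    """
    k = len(levels)
    mean_vectors = np.zeros((k, len(params)))
    mean_vectors[:, 0] = 1.0
    for j in range(1, k):
        mean_vectors[j, j] = 1.0
    rows = []
    for i, j in combinations(range(k), 2):
        c = mean_vectors[i] - mean_vectors[j]
        diff = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        q = abs(diff) / (se / np.sqrt(2.0)) if se > 0 else np.inf
        p_adj = float(stats.studentized_range.sf(q, k, df_resid))
        rows.append({
            "level_a": levels[i], "level_b": levels[j],
            "difference": diff, "se": se, "q": q, "p_adj": p_adj,
            "significant": p_adj < ALPHA,
        })
    return pd.DataFrame(rows)


def compare_groups(records: pd.DataFrame, response: str,
                   grouping: str, group: str = "region_id") -> ModelFit:
    """Mixed-model group comparison with Tukey posthoc contrasts.

    Fits ``response`` (ln-transformed when it is percent saturation)
    on a categorical grouping (``landuse``, ``season`` or ``order``)
    with a region random intercept. The omnibus significance is a
    likelihood-ratio test against the null model; all pairwise
    contrasts are Tukey-adjusted through the studentized range.
    """
    try:
        column = GROUPING_COLUMNS[grouping]
    except KeyError:
        raise ValidationError(
            f"unknown grouping {grouping!r}; expected one of "
            f"{sorted(GROUPING_COLUMNS)}"
        ) from None
    data = _listwise(records, [response, group, column])
    levels = sorted(data[column].unique())
    if len(levels) < 2:
        raise ValidationError(
            f"grouping {grouping!r} has a single level in these records"
        )

    y = data[response].to_numpy(dtype=float)
    endog = np.log(y) if response == "pct_sat" else y
    dummies = pd.get_dummies(
        pd.Categorical(data[column], categories=levels), drop_first=True,
    ).to_numpy(dtype=float)
    exog = sm.add_constant(dummies)
    groups = data[group].to_numpy()

    result = _mixedlm_fit(endog, exog, groups, reml=True)
    params = np.asarray(result.fe_params)
    se = np.asarray(result.bse_fe)
    cov = np.asarray(result.cov_params())[:len(params), :len(params)]
    df_resid = len(endog) - exog.shape[1]
    zcrit = stats.norm.ppf(1 - ALPHA / 2)
    tvals = params / se
    terms = ["intercept"] + [f"{column}[{lv}]" for lv in levels[1:]]
    coef = pd.DataFrame({
        "term": terms,
        "estimate": params,
        "se": se,
        "ci_low": params - zcrit * se,
        "ci_high": params + zcrit * se,
        "df": df_resid,
        "t": tvals,
        "p": 2 * stats.norm.sf(np.abs(tvals)),
    })
    omnibus_p = _lrt_vs_null(endog, exog, groups)
    re_var = float(np.asarray(result.cov_re).ravel()[0]) \
        if result.cov_re.size else 0.0

    return ModelFit(
        coefficients=coef,
        random_effect_variance=re_var,
        residual_variance=float(result.scale),
        n_observations=len(endog),
        n_dropped=len(records) - len(data),
        loglik=float(result.llf),
        null_comparison_p=omnibus_p,
        omnibus_p=omnibus_p,
        contrasts=_tukey_contrasts(levels, params, cov, df_resid),
        meta={"grouping": grouping, "levels": levels,
              "response_transform": "ln" if response == "pct_sat" else None},
    )


def vif_screen(records: pd.DataFrame, terms: Sequence[str],
               threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factor per term; VIF_j = 1/(1 - R2_j).

    Perfect collinearity is reported as infinite VIF (flagged), not an
    exception. Constant columns are rejected because their VIF is
    undefined.
    """
    terms = list(terms)
    if len(terms) < 2:
        raise ValidationError("VIF needs at least two terms")
    data = records[terms].dropna()
    constant = [t for t in terms if data[t].nunique() <= 1]
    if constant:
        raise ValidationError(f"constant column(s) {constant} have no VIF")
    exog = sm.add_constant(data.to_numpy(dtype=float))
    vifs = []
    for j in range(1, exog.shape[1]):
        with np.errstate(divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vifs.append(float(variance_inflation_factor(exog, j)))
    out = pd.DataFrame({"vif": vifs}, index=terms)
    out["flagged"] = out["vif"] >= threshold
    return out
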