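"""Two-stage ecological regression, learning rates, and diagnostics.

Stage one regresses log mean bias on log city population,

    ln(b_i) = C + beta1 * ln(N_i) + eps_i,

so beta1 estimates the bias scaling exponent (-delta * alpha under the
forward model) and eps_i are the per-city scaling deviations.  Stage two
regresses those deviations on the diversity adjustment ln(f1 - f1^2) and
the segregation regressor s1 + s2,

    eps_i = C2 + beta2 * ln(f1 - f1^2) + beta3 * (s1 + s2) + xi_i.

Learning-rate estimates follow as alpha_scaling = -beta1 / delta and
alpha_diversity = -beta2 (signs chosen so that a positive learning rate
means bias falls with exposure).  Cities are equally weighted: plain OLS,
with an optional respondent-count weighting that is off by default.

The two-stage estimates equal the joint single-regression estimates only
when the stage-two regressors are uncorrelated with ln N in the sample;
with correlated designs they differ by O(1/n) terms.  See the methods
note for the partial-R^2 convention (nested-model increments averaged
over addition orders).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import (
    AdjustmentFit,
    BiasObservation,
    City,
    LearningRateEstimates,
    ScalingFit,
    ZeroDiversityError,
)
from .scaling import diversity_adjustment, segregation_adjustment
from .segregation import all_measures

logger = logging.getLogger(__name__)

_ZERO_VAR = 1e-12


def fit_scaling(
    observations: Sequence[BiasObservation],
    cities: Sequence[City],
    *,
    min_responses: int = 500,
    weighted: bool = False,
) -> ScalingFit:
    """Stage-one OLS of ln(mean bias) on ln(population).

    Cities are retained when their observation has more than
    ``min_responses`` respondents (500 by default; 250 and 1000 are the
    usual robustness alternates).  Cities with nonpositive mean bias are
    excluded with a logged warning.  Unweighted OLS by default;
    ``weighted=True`` weights cities by respondent counts.
    """
    by_id = {c.city_id: c for c in cities}
    rows = []
    for obs in observations:
        if obs.n_respondents <= min_responses:
            continue
        city = by_id.get(obs.city_id)
        if city is None:
            logger.warning("observation for %s has no matching city; skipped", obs.city_id)
            continue
        if obs.b <= 0:
            logger.warning("city %s excluded: nonpositive mean bias %s", obs.city_id, obs.b)
            continue
        rows.append((obs.city_id, np.log(city.total), np.log(obs.b), obs.n_respondents))
    if len(rows) < 3:
        raise ValueError(
            f"only {len(rows)} cities pass the min_responses > {min_responses} filter; "
            "need at least 3 for the scaling fit"
        )
    ids, ln_n, ln_b, n_resp = zip(*rows)
    x = sm.add_constant(np.asarray(ln_n))
    y = np.asarray(ln_b)
    if weighted:
        model = sm.WLS(y, x, weights=np.asarray(n_resp, dtype=float))
    else:
        model = sm.OLS(y, x)
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    r2 = float(res.rsquared)
    if np.ptp(y) == 0 or not np.isfinite(r2):
        r2 = 0.0  # constant outcome: no variance to explain
    return ScalingFit(
        C=float(res.params[0]),
        beta1=float(res.params[1]),
        se_beta1=float(res.bse[1]),
        ci_beta1=(float(ci[1, 0]), float(ci[1, 1])),
        residuals=pd.Series(res.resid, index=pd.Index(ids, name="city_id")),
        r2=r2,
        n_cities=len(rows),
    )


def _stage_two_design(
    fit: ScalingFit,
    cities: Sequence[City],
    seg_vectors: Mapping[str, Sequence],
    measure: str,
) -> tuple[pd.DataFrame, list[str]]:
    by_id = {c.city_id: c for c in cities}
    rows, dropped = [], []
    for city_id, eps in fit.residuals.items():
        city = by_id[city_id]
        try:
            d = diversity_adjustment(float(city.group_fractions[0]))
        except ZeroDiversityError:
            logger.warning("city %s excluded from stage two: single-group city", city_id)
            dropped.append(city_id)
            continue
        vec1, vec2 = seg_vectors[city_id]
        s1 = vec1.value(measure) if hasattr(vec1, "value") else float(vec1)
        s2 = vec2.value(measure) if hasattr(vec2, "value") else float(vec2)
        s = segregation_adjustment(s1, s2)
        rows.append((city_id, eps, d, s))
    frame = pd.DataFrame(rows, columns=["city_id", "eps", "diversity_adj", "seg_sum"])
    return frame.set_index("city_id"), dropped


def _r2(y: np.ndarray, cols: list[np.ndarray]) -> float:
    """R^2 of y on an intercept plus the given columns (0 if no columns)."""
    if not cols:
        return 0.0
    x = sm.add_constant(np.column_stack(cols))
    return float(sm.OLS(y, x).fit().rsquared)


def fit_adjustments(
    fit: ScalingFit,
    cities: Sequence[City],
    seg_vectors: Mapping[str, Sequence] | None = None,
    measure: str = "mean_deviance",
) -> AdjustmentFit:
    """Stage-two OLS of scaling deviations on diversity and segregation terms.

    ``seg_vectors`` maps city_id to the pair of per-group
    :class:`SegregationVector` (or plain per-group values of the selected
    measure); if omitted, the selected measure is computed from the cities.
    A regressor with (numerically) zero variance is dropped -- its
    coefficient and variance share are reported as 0 -- with a warning.
    Partial R^2 values are nested-model increments averaged over the two
    addition orders, expressed as shares of the *deviation* variance;
    ``r2_total_model`` is the share of ln b variance explained by all
    three terms together.
    """
    if seg_vectors is None:
        from .segregation import measure as _single_measure

        seg_vectors = {
            c.city_id: (_single_measure(c, 0, measure), _single_measure(c, 1, measure))
            for c in cities
            if c.city_id in fit.residuals.index
        }
    design, dropped = _stage_two_design(fit, cities, seg_vectors, measure)
    if len(design) < 3:
        raise ValueError(f"only {len(design)} cities usable in stage two; need at least 3")
    eps = design["eps"].to_numpy()
    d = design["diversity_adj"].to_numpy()
    s = design["seg_sum"].to_numpy()

    use_d = float(np.std(d)) > _ZERO_VAR
    use_s = float(np.std(s)) > _ZERO_VAR
    if not use_d:
        logger.warning("diversity adjustment has zero variance; its coefficient is fixed at 0")
    if not use_s:
        logger.warning("segregation sum has zero variance; its coefficient is fixed at 0")

    cols, names = [], []
    if use_d:
        cols.append(d)
        names.append("diversity_adj")
    if use_s:
        cols.append(s)
        names.append("seg_sum")
    x = sm.add_constant(np.column_stack(cols)) if cols else np.ones((len(eps), 1))
    res = sm.OLS(eps, x).fit()
    ci = res.conf_int(alpha=0.05)

    def _coef(name: str) -> tuple[float, float, tuple[float, float]]:
        if name not in names:
            return 0.0, 0.0, (0.0, 0.0)
        j = names.index(name) + 1  # skip intercept
        return float(res.params[j]), float(res.bse[j]), (float(ci[j, 0]), float(ci[j, 1]))

    beta2, se2, ci2 = _coef("diversity_adj")
    beta3, se3, ci3 = _coef("seg_sum")

    r2_full = _r2(eps, cols)
    r2_d_only = _r2(eps, [d]) if use_d else 0.0
    r2_s_only = _r2(eps, [s]) if use_s else 0.0
    # order-averaged nested increments (first-in vs last-in)
    r2_div = 0.5 * (r2_d_only + (r2_full - r2_s_only)) if use_d else 0.0
    r2_seg = 0.5 * (r2_s_only + (r2_full - r2_d_only)) if use_s else 0.0
    r2_total = fit.r2 + (1.0 - fit.r2) * r2_full

    return AdjustmentFit(
        C2=float(res.params[0]),
        beta2=beta2, se_beta2=se2, ci_beta2=ci2,
        beta3=beta3, se_beta3=se3, ci_beta3=ci3,
        residuals=pd.Series(res.resid, index=design.index),
        r2_diversity=r2_div,
        r2_segregation=r2_seg,
        r2_total_model=r2_total,
        measure=measure,
        dropped=tuple(dropped),
    )


def estimate_learning_rates(
    sfit: ScalingFit, afit: AdjustmentFit, delta: float = 1.0 / 6.0
) -> LearningRateEstimates:
    """Learning rates from the two fits: alpha_scaling = -beta1/delta, alpha_diversity = -beta2.

    The forward model gives beta1 = -delta*alpha and beta2 = -alpha, so the
    sign flip makes a positive learning rate mean bias decreasing with
    exposure.  CIs are the linearly transformed coefficient CIs (exact for
    a scalar multiple).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    a_s = -sfit.beta1 / delta
    ci_s = tuple(sorted((-sfit.ci_beta1[0] / delta, -sfit.ci_beta1[1] / delta)))
    a_d = -afit.beta2
    ci_d = tuple(sorted((-afit.ci_beta2[0], -afit.ci_beta2[1])))
    return LearningRateEstimates(
        alpha_scaling=a_s, ci_alpha_scaling=ci_s,
        alpha_diversity=a_d, ci_alpha_diversity=ci_d,
        delta_assumed=delta,
    )


def variance_inflation(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of every column of a regressor table.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from regressing column j on the
    other columns plus an intercept.  Perfectly collinear columns report
    ``inf`` rather than raising.
    """
    design = pd.DataFrame(design)
    if design.shape[1] < 2:
        raise ValueError("need at least 2 regressors for VIFs")
    if design.shape[0] < 3:
        raise ValueError("need at least 3 rows for VIFs")
    out = {}
    values = design.to_numpy(dtype=float)
    for j, name in enumerate(design.columns):
        others = np.delete(values, j, axis=1)
        r2 = _r2(values[:, j], [others[:, k] for k in range(others.shape[1])])
        out[name] = np.inf if r2 >= 1.0 - _ZERO_VAR else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def variance_decomposition(sfit: ScalingFit, afit: AdjustmentFit) -> dict[str, float]:
    """Shares of ln b variance explained by scaling, diversity, and segregation.

    The scaling share is the stage-one R^2; diversity and segregation
    shares are the order-averaged stage-two increments rescaled by the
    deviation variance fraction (1 - R^2_scaling), so the three shares sum
    to the total model R^2 (<= 1).
    """
    scale = 1.0 - sfit.r2
    return {
        "scaling": sfit.r2,
        "diversity": scale * afit.r2_diversity,
        "segregation": scale * afit.r2_segregation,
    }


def fit_individual(
    responses: pd.DataFrame,
    city_covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Logistic regression of the positive-bias indicator on city + individual covariates.

    ``responses`` needs columns city_id, d_biep, and either already-recoded
    ``race`` / ``edu3`` columns or raw ``race_raw`` / ``edu14`` (recoded
    here via :mod:`urbanbias.io`), plus ``birth_sex``.  ``city_covariates``
    is indexed by city_id with columns ln_N, diversity_adj, seg_sum.  The
    outcome is 1{d_biep > 0}.  Demographic categories with no respondents
    are dropped with a warning; a degenerate outcome (all positive or all
    nonpositive) raises instead of returning a silent estimate.

    Returns a coefficient table with columns coef, se, z, p.
    """
    from . import io as _io  # local import to avoid a cycle

    df = responses.copy()
    if "race" not in df.columns:
        df["race"] = df["race_raw"].map(_io.recode_race)
    if "edu3" not in df.columns:
        df["edu3"] = df["edu14"].map(_io.recode_education)
    y = (df["d_biep"] > 0).astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError(
            "degenerate outcome: every respondent is on the same side of d_biep = 0 "
            "(perfect separation; no logistic estimate is reported)"
        )
    cov = city_covariates.loc[df["city_id"]].reset_index(drop=True)
    x_parts = [cov[["ln_N", "diversity_adj", "seg_sum"]].reset_index(drop=True)]
    expected = {
        "race": ("other-base", ["White", "Black", "Multiracial"]),
        "edu3": ("some-college-or-grad", ["HS-or-below", "advanced"]),
        "birth_sex": (None, None),
    }
    for col, (base, non_base) in expected.items():
        present = [c for c in pd.unique(df[col].dropna())]
        if non_base is not None:
            empty = [lvl for lvl in non_base if lvl not in present]
            if empty:
                logger.warning("covariate %s: empty categories %s dropped from the model",
                               col, empty)
            keep_levels = [lvl for lvl in non_base if lvl in present]
        else:
            ref = sorted(present)[0] if present else None
            keep_levels = [lvl for lvl in sorted(present) if lvl != ref]
        dummies = pd.get_dummies(df[col], prefix=col, dtype=float)
        keep = [f"{col}_{lvl}" for lvl in keep_levels if f"{col}_{lvl}" in dummies.columns]
        x_parts.append(dummies[keep].reset_index(drop=True))
    x = sm.add_constant(pd.concat(x_parts, axis=1))
    try:
        res = sm.Logit(y, x.astype(float)).fit(disp=0)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(f"logistic regression failed ({exc}); likely separation") from exc
    return pd.DataFrame(
        {"coef": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues}
    )
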