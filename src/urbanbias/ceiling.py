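"""Split-half noise-ceiling estimation for city-level mean bias.

City mean D-scores are noisy: each city's mean is estimated from a finite
set of respondents whose individual scores fluctuate.  Even a perfect
model of the true city means would therefore leave variance unexplained.
The noise ceiling bounds the attainable R^2: for each of ``n_splits``
random partitions of every city's respondents into two halves, the
per-city half means are correlated across cities

* between the two halves (lower bound), and
* each half against the full-sample means, averaged (upper bound),

then both are averaged over splits.  With between-city variance tau^2,
within-city variance sigma^2, and n respondents per city, the lower bound
converges to the attenuation tau^2 / (tau^2 + 2 sigma^2 / n).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NoiseCeiling

logger = logging.getLogger(__name__)


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(np.corrcoef(a, b)[0, 1])
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def estimate(
    responses: pd.DataFrame,
    n_splits: int = 500,
    *,
    seed: int = 0,
    method: str = "pearson",
) -> NoiseCeiling:
    """Split-half noise ceiling from a respondent table.

    ``responses`` needs columns ``city_id`` and ``d_biep``.  Cities with a
    single respondent cannot be split and are excluded with a warning; at
    least two retained cities are required.  When a city has an odd number
    of respondents the extra one is assigned to a half uniformly at random
    per split.  Pearson correlations by default (``method='spearman'`` for
    ranks).  Deterministic given ``seed``.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    groups = []
    for city_id, grp in responses.groupby("city_id", sort=True):
        vals = grp["d_biep"].to_numpy(dtype=float)
        if len(vals) < 2:
            logger.warning("city %s has a single respondent; excluded from the noise ceiling", city_id)
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need at least 2 cities with >= 2 respondents")
    rng = np.random.default_rng(seed)
    full = np.array([g.mean() for g in groups])
    k = len(groups)
    per_split = []
    for _ in range(n_splits):
        m1 = np.empty(k)
        m2 = np.empty(k)
        for j, vals in enumerate(groups):
            n = len(vals)
            perm = rng.permutation(n)
            cut = n // 2
            if n % 2 == 1 and rng.random() < 0.5:
                cut += 1
            m1[j] = vals[perm[:cut]].mean()
            m2[j] = vals[perm[cut:]].mean()
        lower = _corr(m1, m2, method)
        upper = 0.5 * (_corr(m1, full, method) + _corr(m2, full, method))
        per_split.append((lower, upper))
    arr = np.asarray(per_split)
    return NoiseCeiling(
        lower=float(arr[:, 0].mean()),
        upper=float(arr[:, 1].mean()),
        n_splits=n_splits,
        per_split_values=tuple(map(tuple, arr)),
    )


def corrected_r2(r2: float, ceiling: NoiseCeiling) -> float:
    """Model R^2 rescaled by the noise ceiling (divided by lower-bound squared)."""
    if ceiling.lower <= 0:
        raise ValueError("noise ceiling lower bound must be positive to correct R^2")
    return r2 / ceiling.lower**2
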