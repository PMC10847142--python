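"""Forward model: heterogeneous-mixing urban scaling and the bias learning curve.

Per-capita social interactions in a city of population N split into a
within-group and a between-group component,

    k = N^delta * [ sum_g f_g^2 (1 + h_in_g)
                    + sum_g sum_{j!=g} f_g f_j (1 - h_bet_g) ],

with group fractions f_g, within-group boost h_in_g and between-group
reduction h_bet_g (each group avoids all out-groups at the same rate).
Mean implicit bias is then a power-law learning curve of between-group
exposure, b ~ k_inter^(-alpha), which for two groups factorizes into a
scaling term, a diversity term, and a segregation term:

    b = prefactor * N^(-delta*alpha) * (f1 - f1^2)^(-alpha)
        * (2 - h1 - h2)^(-alpha).

All proportionality constants are explicit (``prefactor``, default 1), so
the model is deterministic and its logarithm is exactly linear in
[ln N, ln(f1 - f1^2), ln(2 - h1 - h2)] with coefficients
(-delta*alpha, -alpha, -alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    City,
    ModelParameters,
    OverSegregatedError,
    SegregationVector,
    ZeroDiversityError,
)


@dataclass(frozen=True)
class InteractionSummary:
    """Per-capita interactions split into within- and between-group parts."""

    k_total: float
    k_within: float
    k_between: float


def per_capita_interactions(
    city: City,
    params: ModelParameters,
    *,
    h_in: "np.ndarray | float | None" = None,
    h_bet: "np.ndarray | float | None" = None,
) -> InteractionSummary:
    """Evaluate the heterogeneous-mixing interaction model for one city.

    ``h_in`` / ``h_bet`` override the per-group rates (scalar or length-G
    array); by default every group uses ``params.h_in`` and
    ``params.h_bet0``.  The proportionality constant is fixed to 1.
    """
    f = city.group_fractions
    g = city.n_groups
    h_in_arr = np.broadcast_to(np.asarray(params.h_in if h_in is None else h_in, dtype=float), (g,))
    h_bet_arr = np.broadcast_to(np.asarray(params.h_bet0 if h_bet is None else h_bet, dtype=float), (g,))
    if np.any(h_bet_arr > 1.0):
        raise ValueError("h_bet > 1 would give a negative between-group interaction rate")
    scale = city.total**params.delta
    within = float(np.sum(f**2 * (1.0 + h_in_arr))) * scale
    cross = f[:, None] * f[None, :] * (1.0 - h_bet_arr)[:, None]
    np.fill_diagonal(cross, 0.0)
    between = float(cross.sum()) * scale
    return InteractionSummary(k_total=within + between, k_within=within, k_between=between)


def diversity_adjustment(f1: float) -> float:
    """ln(f1 - f1^2): log of the two-group mixing term.

    Symmetric under f1 <-> 1 - f1 and maximal at a 50/50 composition.
    Raises :class:`ZeroDiversityError` at f1 in {0, 1}; the caller decides
    the exclusion policy for single-group cities.
    """
    if not 0.0 < f1 < 1.0:
        raise ZeroDiversityError(f"group fraction {f1} gives zero diversity term")
    return math.log(f1 - f1 * f1)


def segregation_adjustment(s1: float, s2: float) -> float:
    """The segregation regressor s1 + s2.

    Arises from linearizing ln(2 - h1 - h2) with h_g linear in s_g; the
    linearization constants are absorbed into the fitted coefficients, so
    the regressor itself is simply the sum of the two groups' segregation
    measures.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("segregation measures must be nonnegative")
    return s1 + s2


def _segregation_pair(seg: "tuple | list") -> tuple[float, float]:
    vals = []
    for item in seg:
        if isinstance(item, SegregationVector):
            raise TypeError(
                "pass plain segregation values (select a measure first), "
                "e.g. seg_vec.value('mean_deviance')"
            )
        vals.append(float(item))
    if len(vals) != 2:
        raise ValueError("expected segregation values for exactly two groups")
    return vals[0], vals[1]


def expected_bias(
    city: City,
    params: ModelParameters,
    seg: "tuple[float, float]",
    *,
    linearized: bool = False,
) -> float:
    """Noise-free mean bias of a two-group city under the learning-curve model.

    ``seg`` holds the two groups' residential segregation values; the
    between-group reductions are the linear proxy
    h_g = h_bet0 + b_bet * s_g.  With ``linearized=True`` the segregation
    factor (2 - h1 - h2)^(-alpha) is replaced by its small-(h1+h2)
    linearized form exp(-alpha * (ln 2 - (h1 + h2)/2)), which makes ln b
    exactly linear in the regressors used by the two-stage fit.
    """
    if city.n_groups != 2:
        raise ValueError("expected_bias is defined for two-group cities")
    s1, s2 = _segregation_pair(seg)
    f1 = float(city.group_fractions[0])
    div = f1 - f1 * f1
    if div <= 0.0:
        raise ZeroDiversityError(
            f"city {city.city_id!r}: diversity term f1 - f1^2 = {div} is not positive"
        )
    h1 = params.h_bet0 + params.b_bet * s1
    h2 = params.h_bet0 + params.b_bet * s2
    rem = 2.0 - h1 - h2
    if rem <= 0.0:
        raise OverSegregatedError(
            f"city {city.city_id!r}: 2 - h1 - h2 = {rem} <= 0 (over-segregated)"
        )
    a = params.alpha
    if linearized:
        seg_factor = math.exp(-a * (math.log(2.0) - (h1 + h2) / 2.0))
    else:
        seg_factor = rem ** (-a)
    return params.prefactor * city.total ** (-params.delta * a) * div ** (-a) * seg_factor


def doubling_gain(delta: float) -> float:
    """Percent increase in per-capita interactions when N doubles: 100 (2^delta - 1).

    At the reference exponent delta = 1/6 this is ~12%, independent of the
    starting N (scale invariance).
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    return 100.0 * (2.0**delta - 1.0)
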