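"""Aspatial residential segregation measures from tract-level counts.

Four classic unevenness/exposure indices, each computed per group from an
M x G table of tract counts:

* ``mean_deviance``  -- mean absolute deviation of tract group shares from
  the city share (unweighted over tracts).
* ``dissimilarity``  -- the tract-population-weighted, normalized version
  (the dissimilarity index D).
* ``gini``           -- the segregation Gini coefficient over all ordered
  tract pairs.
* ``correlation_ratio`` -- the eta-squared / correlation ratio, i.e. the
  isolation index rescaled so that an even distribution gives 0 and
  complete segregation gives 1.

All four are scale invariant (multiplying every count by a positive
integer changes nothing), invariant to tract order, zero when every
tract's group share equals the city share, and the last three are 1 under
complete segregation.
"""

from __future__ import annotations

import numpy as np

from .datatypes import City, EmptyTractError, SegregationVector

MEASURE_NAMES = ("mean_deviance", "dissimilarity", "gini", "correlation_ratio")


def _shares(city: City, group: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Tract group shares, tract totals, and the city share p = N_g / N."""
    totals = city.tract_totals
    empty = np.nonzero(totals == 0)[0]
    if empty.size:
        raise EmptyTractError(
            f"city {city.city_id!r}: tract(s) {empty.tolist()} have zero population"
        )
    n_g = city.group_totals[group]
    if n_g == 0:
        raise ValueError(f"city {city.city_id!r}: group {group} has zero population")
    shares = city.tract_counts[:, group] / totals
    p = n_g / city.total
    return shares, totals, p


def _check_two_sided(city: City, group: int, p: float, what: str) -> None:
    if p >= 1.0:
        raise ValueError(
            f"city {city.city_id!r}: {what} undefined when group {group} is the "
            "entire population (denominator p(1-p) is zero)"
        )


def mean_deviance(city: City, group: int) -> float:
    """Mean absolute deviation of tract group shares from the city share.

    (1/M) * sum_m |N_{g,m}/N_m - N_g/N|.  Interpretable as the fraction of
    the group that would have to move to even the distribution; insensitive
    to movement between tracts that are both above (or both below) the city
    share, and blind to tract population sizes.
    """
    shares, _, p = _shares(city, group)
    return float(np.abs(shares - p).mean())


def dissimilarity(city: City, group: int) -> float:
    """Dissimilarity index D: population-weighted, normalized unevenness.

    sum_m |N_{g,m}/N_m - p| * N_m / (2 N p (1 - p)), with p = N_g / N.
    Ranges over [0, 1]; 1 iff every tract holds a single group.
    """
    shares, totals, p = _shares(city, group)
    _check_two_sided(city, group, p, "dissimilarity")
    num = float(np.sum(np.abs(shares - p) * totals))
    return num / (2.0 * city.total * p * (1.0 - p))


def gini(city: City, group: int) -> float:
    """Segregation Gini coefficient over all ordered tract pairs.

    sum_{m,l} |share_m - share_l| N_m N_l / (2 N^2 p (1-p)).  Diagonal
    terms are zero; the ordered double sum with the 1/2 factor matches the
    usual pairwise mean absolute difference.  Always >= dissimilarity.
    """
    shares, totals, p = _shares(city, group)
    _check_two_sided(city, group, p, "gini")
    # Weighted pairwise sum via the sorted-values identity
    #   sum_{m,l} w_m w_l |x_m - x_l| = 2 sum_i w_i x_i (2 C_i - w_i - W)
    # (C_i = cumulative weight through i after sorting), O(M log M) instead
    # of materializing the M x M difference matrix.
    order = np.argsort(shares, kind="stable")
    x = shares[order]
    w = totals[order].astype(float)
    c = np.cumsum(w)
    num = 2.0 * float(np.sum(w * x * (2.0 * c - w - c[-1])))
    return num / (2.0 * city.total**2 * p * (1.0 - p))


def correlation_ratio(city: City, group: int, *, literal: bool = False) -> float:
    """Correlation ratio (eta^2), the normalized isolation/exposure index.

    Computed as ((sum_m N_{g,m}^2 / N_m) / N_g - p) / (1 - p): the
    group-share-weighted mean tract share (isolation index), rescaled so an
    even distribution gives 0 and complete segregation gives 1.

    With ``literal=True`` the per-tract totals are omitted from the sum
    (sum_m N_{g,m}^2 / (N_g (1-p)) - p/(1-p)).  That variant is *not* a
    normalized index -- it fails both boundary checks above and grows with
    tract counts -- and exists only for comparison.
    """
    _, totals, p = _shares(city, group)
    _check_two_sided(city, group, p, "correlation ratio")
    counts = city.tract_counts[:, group].astype(float)
    n_g = float(city.group_totals[group])
    if literal:
        return float(np.sum(counts**2) / (n_g * (1.0 - p)) - p / (1.0 - p))
    isolation = float(np.sum(counts**2 / totals)) / n_g
    return (isolation - p) / (1.0 - p)


def all_measures(city: City) -> list[SegregationVector]:
    """All four measures for every group of the city. Errors propagate."""
    out = []
    for g in range(city.n_groups):
        out.append(
            SegregationVector(
                group=g,
                mean_deviance=mean_deviance(city, g),
                dissimilarity=dissimilarity(city, g),
                gini=gini(city, g),
                correlation_ratio=correlation_ratio(city, g),
            )
        )
    return out


def measure(city: City, group: int, name: str) -> float:
    """Dispatch a single measure by name (the generic s_{g,i})."""
    if name == "mean_deviance":
        return mean_deviance(city, group)
    if name == "dissimilarity":
        return dissimilarity(city, group)
    if name == "gini":
        return gini(city, group)
    if name == "correlation_ratio":
        return correlation_ratio(city, group)
    raise KeyError(f"unknown segregation measure {name!r}")
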