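"""Shared containers and error types for the city-bias pipeline.

The central object is a :class:`City`: an M x G table of tract-level
population counts for G demographic groups (G = 2 throughout the bias
pipeline, matching the White/Black contrast of the racial IAT).  All
derived quantities -- group totals, the city total, group fractions --
are computed from that table, never stored separately, so the count
conservation invariants hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class DegenerateCityError(ValueError):
    """A city violates a precondition of the forward model."""


class ZeroDiversityError(DegenerateCityError):
    """The two-group mixing term f1 - f1^2 is zero (single-group city)."""


class OverSegregatedError(DegenerateCityError):
    """Effective between-group reduction leaves no interactions (2 - h1 - h2 <= 0)."""


class EmptyTractError(ValueError):
    """A tract with zero total population was passed to a segregation measure."""


@dataclass(frozen=True)
class City:
    """One city: tract-level group counts N_{g,m} for groups g and tracts m.

    Parameters
    ----------
    city_id : str
        Stable identifier (CBSA-like code in real data).
    tract_counts : (M, G) array of nonnegative integers
        Row m holds the population of each group in tract m.
    """

    city_id: str
    tract_counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.tract_counts)
        if counts.ndim != 2:
            raise ValueError("tract_counts must be a 2-D (tracts x groups) table")
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("city needs at least one tract and one group")
        if np.any(counts < 0):
            raise ValueError(f"negative tract counts in city {self.city_id!r}")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("tract_counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.sum() <= 0:
            raise ValueError(f"city {self.city_id!r} has no population")
        object.__setattr__(self, "tract_counts", counts)
        self.tract_counts.setflags(write=False)

    @property
    def n_tracts(self) -> int:
        return self.tract_counts.shape[0]

    @property
    def n_groups(self) -> int:
        return self.tract_counts.shape[1]

    @property
    def tract_totals(self) -> np.ndarray:
        """N_m: total population of each tract."""
        return self.tract_counts.sum(axis=1)

    @property
    def group_totals(self) -> np.ndarray:
        """N_g: citywide population of each group."""
        return self.tract_counts.sum(axis=0)

    @property
    def total(self) -> int:
        """N: total city population."""
        return int(self.tract_counts.sum())

    @property
    def group_fractions(self) -> np.ndarray:
        """f_g = N_g / N."""
        return self.group_totals / self.total


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the forward scaling / learning-curve model.

    Attributes
    ----------
    delta : float
        Baseline interaction scaling exponent (k ~ N^delta); 1/6 in the
        reference theory of urban scaling.
    alpha : float
        Learning rate of the power-law learning curve b ~ k_inter^(-alpha),
        in (0, 1); larger alpha means faster unlearning of bias with
        out-group exposure.
    h_in : float
        Within-group interaction boost (>= 0); groups interact with their
        in-group at relative rate 1 + h_in.
    h_bet0 : float
        Baseline between-group interaction reduction (intercept of the
        linear proxy h_g = h_bet0 + b_bet * s_g on residential segregation).
    b_bet : float
        Slope of the segregation proxy.
    prefactor : float
        Explicit proportionality constant of the bias scaling law
        (defaults to 1; fits absorb it into the intercept).
    noise_sd : float
        Standard deviation of additive noise on ln b (multiplicative on b).
    individual_sd : float
        Respondent-level standard deviation of D-scores around the city mean.
    """

    delta: float = 1.0 / 6.0
    alpha: float = 0.2
    h_in: float = 0.0
    h_bet0: float = 0.1
    b_bet: float = 0.5
    prefactor: float = 1.0
    noise_sd: float = 0.1
    individual_sd: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.h_in < 0:
            raise ValueError("h_in must be nonnegative")
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")
        if self.noise_sd < 0 or self.individual_sd < 0:
            raise ValueError("noise scales must be nonnegative")


@dataclass(frozen=True)
class BiasObservation:
    """City-year mean bias (mean D-score) with its respondent count."""

    city_id: str
    year: int
    b: float
    n_respondents: int

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("mean bias b must be positive (its log is modelled)")
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")


@dataclass(frozen=True)
class SegregationVector:
    """The four aspatial residential segregation measures for one group."""

    group: int
    mean_deviance: float
    dissimilarity: float
    gini: float
    correlation_ratio: float

    def value(self, measure: str) -> float:
        """Return the measure selected by name (the generic s_{g} alias)."""
        try:
            return float(getattr(self, measure))
        except AttributeError:
            raise KeyError(
                f"unknown segregation measure {measure!r}; expected one of "
                "mean_deviance, dissimilarity, gini, correlation_ratio"
            ) from None


@dataclass(frozen=True)
class CityPanel:
    """Multi-year series of structural variables and bias for one city.

    ``series`` is a DataFrame indexed by year with columns
    ``ln_N``, ``diversity_adj``, ``seg_sum``, ``ln_b``.
    """

    city_id: str
    series: pd.DataFrame

    PANEL_COLUMNS = ("ln_N", "diversity_adj", "seg_sum", "ln_b")

    def __post_init__(self) -> None:
        missing = [c for c in self.PANEL_COLUMNS if c not in self.series.columns]
        if missing:
            raise ValueError(f"panel for {self.city_id!r} missing columns {missing}")
        years = np.asarray(self.series.index)
        if len(years) < 2:
            raise ValueError("panel needs at least two years")
        steps = np.diff(years)
        if np.any(steps <= 0) or len(set(steps.tolist())) > 1:
            raise ValueError("panel years must be strictly increasing and equally spaced")

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.series.index)

    @property
    def n_years(self) -> int:
        return len(self.series)


@dataclass(frozen=True)
class ScalingFit:
    """First-stage log-log OLS of mean bias on city population (ln b ~ C + beta1 ln N)."""

    C: float
    beta1: float
    se_beta1: float
    ci_beta1: tuple[float, float]
    residuals: pd.Series  # scaling deviations, indexed by city_id
    r2: float
    n_cities: int


@dataclass(frozen=True)
class AdjustmentFit:
    """Second-stage OLS of scaling deviations on diversity and segregation terms."""

    C2: float
    beta2: float
    se_beta2: float
    ci_beta2: tuple[float, float]
    beta3: float
    se_beta3: float
    ci_beta3: tuple[float, float]
    residuals: pd.Series  # xi_i, indexed by city_id
    r2_diversity: float
    r2_segregation: float
    r2_total_model: float
    measure: str = "mean_deviance"
    dropped: tuple[str, ...] = ()


@dataclass(frozen=True)
class LearningRateEstimates:
    """Two independent learning-rate estimates and their 95% CIs."""

    alpha_scaling: float
    ci_alpha_scaling: tuple[float, float]
    alpha_diversity: float
    ci_alpha_diversity: tuple[float, float]
    delta_assumed: float


@dataclass(frozen=True)
class NoiseCeiling:
    """Split-half noise ceiling bounds for city-level mean bias."""

    lower: float
    upper: float
    n_splits: int
    per_split_values: tuple[tuple[float, float], ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


@dataclass(frozen=True)
class PrecedenceSummary:
    """Percentage of cities with Granger-style temporal precedence evidence."""

    direction: tuple[str, str]
    lag: int
    pct_significant: float
    se_bootstrap: float
    n_cities: int
    alpha_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_significant <= 100.0:
            raise ValueError("pct_significant must lie in [0, 100]")
        if self.se_bootstrap < 0:
            raise ValueError("se_bootstrap must be nonnegative")
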