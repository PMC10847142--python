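"""Synthetic cities, respondents, and multi-year panels.

Everything downstream of this module (segregation indices, the two-stage
fit, noise ceilings, temporal precedence) is exercised on data produced
here, so no external census or IAT download is needed.

What the generator emulates
---------------------------
* city populations spanning the CBSA range, drawn log-uniform;
* two demographic groups with a varying majority fraction;
* census-tract-sized neighborhoods (~4,000 inhabitants) whose group
  shares scatter around the city share with a tunable unevenness
  ("seg_level"): tract shares are Beta distributed with mean equal to
  the city share and concentration kappa = (1 - s) / s, so s is the
  large-tract limit of the correlation ratio (s = 0 gives a perfectly
  even city, s -> 1 gives single-group tracts);
* counts are integer-rounded by largest-remainder apportionment so group
  and city totals are conserved exactly;
* mean bias generated from the forward learning-curve model with
  multiplicative (log-additive) noise;
* respondent-level D-scores scattered around the city mean;
* multi-year panels of structural variables (random walks with drift)
  optionally coupled to bias at a lag, for temporal-precedence analyses.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .datatypes import BiasObservation, City, CityPanel, ModelParameters
from .scaling import expected_bias
from .segregation import measure as seg_measure

logger = logging.getLogger(__name__)

DEFAULT_POP_RANGE = (5e4, 2e7)
DEFAULT_TRACT_SIZE = 4000
DEFAULT_SEG_RANGE = (0.02, 0.3)
DEFAULT_MAJORITY_RANGE = (0.55, 0.95)

# Default respondent covariate distributions (configurable per call).
DEFAULT_RACE_PROBS = {
    "White": 0.62,
    "Black": 0.10,
    "Asian": 0.08,
    "Multiracial": 0.05,
    "Other": 0.10,
    "Unknown": 0.05,
}
DEFAULT_SEX_PROBS = {"f": 0.6, "m": 0.4}
# edu_14 codes 1..14, weighted towards some-college/college-graduate
# (IAT volunteer samples skew educated).
DEFAULT_EDU_PROBS = {
    1: 0.01, 2: 0.02, 3: 0.05, 4: 0.10, 5: 0.14, 6: 0.20, 7: 0.18,
    8: 0.08, 9: 0.10, 10: 0.03, 11: 0.04, 12: 0.02, 13: 0.02, 14: 0.01,
}


def _apportion(quota: np.ndarray, caps: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` units along ``quota``.

    Returns integer counts summing exactly to ``total`` with counts[m] <=
    caps[m]; quotas are first rescaled to sum to ``total``.
    """
    caps = np.asarray(caps, dtype=np.int64)
    if total > caps.sum():
        raise ValueError("total exceeds the sum of caps")
    quota = np.asarray(quota, dtype=float)
    qsum = quota.sum()
    if qsum <= 0:
        quota = caps.astype(float)
        qsum = quota.sum()
    scaled = np.minimum(quota * (total / qsum), caps)
    counts = np.floor(scaled).astype(np.int64)
    remainder = total - int(counts.sum())
    # Distribute leftover units by descending fractional part among tracts
    # with headroom; loop converges because sum(caps) >= total.
    while remainder > 0:
        frac = scaled - counts
        frac[counts >= caps] = -1.0
        order = np.argsort(-frac, kind="stable")
        room = order[counts[order] < caps[order]][:remainder]
        counts[room] += 1
        remainder = total - int(counts.sum())
    return counts


def generate_cities(
    params: ModelParameters,
    n_cities: int,
    *,
    pop_range: tuple[float, float] = DEFAULT_POP_RANGE,
    tract_size: int = DEFAULT_TRACT_SIZE,
    seg_level_range: tuple[float, float] = DEFAULT_SEG_RANGE,
    majority_frac_range: tuple[float, float] = DEFAULT_MAJORITY_RANGE,
    seed: int = 0,
) -> list[City]:
    """Generate ``n_cities`` two-group cities with tract-level counts.

    Populations are log-uniform on ``pop_range``; the target group-1
    (majority) fraction is uniform on ``majority_frac_range`` and sets the
    mean of the Beta distribution of tract group shares; each city's
    unevenness level is uniform on ``seg_level_range`` and controls the
    Beta concentration (see module docstring).  The realized city
    composition is whatever the drawn tract shares imply, so the drawn
    unevenness is preserved exactly; at high unevenness with few tracts
    the realized composition can drift from its target, and in the extreme
    a single-group city can arise (downstream stages flag those).
    """
    if n_cities < 0:
        raise ValueError("n_cities must be nonnegative")
    if n_cities == 0:
        return []
    lo_p, hi_p = pop_range
    if not (0 < lo_p <= hi_p):
        raise ValueError(f"invalid pop_range {pop_range}")
    if tract_size < 1:
        raise ValueError("tract_size must be positive")
    if lo_p < 2 * tract_size:
        raise ValueError("pop_range minimum must be at least 2 * tract_size")
    for name, (lo, hi) in (("seg_level_range", seg_level_range),
                           ("majority_frac_range", majority_frac_range)):
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError(f"invalid {name} {(lo, hi)}: need 0 <= lo <= hi < 1")

    rng = np.random.default_rng(seed)
    pops = np.exp(rng.uniform(np.log(lo_p), np.log(hi_p), size=n_cities))
    fracs = rng.uniform(*majority_frac_range, size=n_cities)
    seg_levels = rng.uniform(*seg_level_range, size=n_cities)

    cities: list[City] = []
    for i in range(n_cities):
        n_total = int(round(pops[i]))
        m = max(1, int(round(n_total / tract_size)))
        base, extra = divmod(n_total, m)
        tract_totals = np.full(m, base, dtype=np.int64)
        tract_totals[:extra] += 1
        f1 = fracs[i]
        s = seg_levels[i]
        if s == 0.0:
            shares = np.full(m, f1)
        else:
            kappa = (1.0 - s) / s
            shares = rng.beta(f1 * kappa, (1.0 - f1) * kappa, size=m)
        quotas = shares * tract_totals
        # the realized composition comes from the drawn shares; rescaling the
        # quotas to a pre-set N1 would flatten the drawn unevenness
        g1 = _apportion(quotas, tract_totals, int(round(quotas.sum())))
        counts = np.column_stack([g1, tract_totals - g1])
        cities.append(City(city_id=f"city{i:04d}", tract_counts=counts))
    return cities


def generate_bias(
    cities: Sequence[City],
    params: ModelParameters,
    *,
    seed: int = 0,
    year: int = 2020,
    n_respondents: int = 1000,
    measure: str = "mean_deviance",
    linearized: bool = False,
) -> list[BiasObservation]:
    """Mean bias per city from the forward model plus multiplicative noise.

    ln b = ln(prefactor) - delta*alpha*ln N - alpha*ln(f1 - f1^2)
           - alpha*ln(2 - h1 - h2) + Normal(0, noise_sd),

    with h_g = h_bet0 + b_bet * s_g and s_g the selected segregation
    measure of the generated city.  Cities with a nonpositive diversity
    term (single-group) are excluded with a logged warning, never
    silently dropped.  ``linearized`` selects the linearized segregation
    factor (see :func:`urbanbias.scaling.expected_bias`).
    """
    rng = np.random.default_rng(seed)
    out: list[BiasObservation] = []
    for city in cities:
        noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
        f1 = float(city.group_fractions[0])
        if f1 <= 0.0 or f1 >= 1.0:
            logger.warning(
                "city %s excluded from bias generation: single-group city "
                "(f1 = %.4f gives a nonpositive diversity term)", city.city_id, f1,
            )
            continue
        s1 = seg_measure(city, 0, measure)
        s2 = seg_measure(city, 1, measure)
        b = expected_bias(city, params, (s1, s2), linearized=linearized) * np.exp(noise)
        out.append(BiasObservation(city_id=city.city_id, year=year,
                                   b=float(b), n_respondents=n_respondents))
    return out


def generate_individuals(
    obs: BiasObservation,
    params: ModelParameters,
    *,
    seed: int = 0,
    race_probs: dict[str, float] | None = None,
    edu_probs: dict[int, float] | None = None,
    sex_probs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Respondent-level D-scores and demographics for one city-year.

    Draws ``obs.n_respondents`` rows with d_biep ~ Normal(b, individual_sd)
    and categorical race / edu_14 / birth-sex covariates.  Returns a
    DataFrame with columns city_id, year, d_biep, race_raw, edu14,
    birth_sex (one row per respondent).
    """
    rng = np.random.default_rng(seed)
    n = obs.n_respondents
    races = race_probs or DEFAULT_RACE_PROBS
    edus = edu_probs or DEFAULT_EDU_PROBS
    sexes = sex_probs or DEFAULT_SEX_PROBS

    def _draw(dist: dict, size: int) -> np.ndarray:
        keys = list(dist.keys())
        p = np.asarray([dist[k] for k in keys], dtype=float)
        return rng.choice(np.asarray(keys, dtype=object), size=size, p=p / p.sum())

    d = np.full(n, obs.b) if params.individual_sd == 0 else rng.normal(obs.b, params.individual_sd, n)
    return pd.DataFrame(
        {
            "city_id": obs.city_id,
            "year": obs.year,
            "d_biep": d,
            "race_raw": _draw(races, n),
            "edu14": _draw(edus, n).astype(int),
            "birth_sex": _draw(sexes, n),
        }
    )


def generate_respondents(
    observations: Sequence[BiasObservation],
    params: ModelParameters,
    *,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Respondent tables for many city-years, concatenated (seeded per city)."""
    seq = np.random.SeedSequence(seed)
    child_seeds = seq.spawn(len(observations))
    frames = [
        generate_individuals(o, params, seed=int(cs.generate_state(1)[0] % (2**31)), **kwargs)
        for o, cs in zip(observations, child_seeds)
    ]
    if not frames:
        return pd.DataFrame(columns=["city_id", "year", "d_biep", "race_raw", "edu14", "birth_sex"])
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class Coupling:
    """Lagged dependence between structural variables and bias in panels.

    ``variables`` restricts which structural series take part in the
    coupling (default: all three).
    """

    direction: Literal["structural->bias", "bias->structural", "none"] = "none"
    lag: int = 1
    strength: float = 0.0
    variables: tuple[str, ...] = ("ln_N", "diversity_adj", "seg_sum")


def generate_panel(
    n_cities: int,
    n_years: int,
    coupling: Coupling = Coupling(),
    *,
    seed: int = 0,
    start_year: int = 2011,
    rw_sd: float = 0.05,
    drift_sd: float = 0.02,
    bias_noise_sd: float = 0.05,
) -> list[CityPanel]:
    """Multi-year city panels of (ln N, diversity adj, segregation sum, ln b).

    Structural series are independent Gaussian random walks with per-city
    drift.  Under ``structural->bias`` coupling, ln b_t = a_city +
    strength * sum_v x_{v, t-lag} + noise over the coupled variables;
    under ``bias->structural`` the lagged dependence runs the other way
    (ln b is a random walk feeding each coupled structural series); under
    ``none`` the structural series stay independent random walks and bias
    fluctuates independently around a city-specific level.
    """
    if n_cities < 1:
        raise ValueError("n_cities must be positive")
    if coupling.lag < 0:
        raise ValueError("lag must be nonnegative")
    if n_years <= coupling.lag + 4:
        raise ValueError(
            f"n_years = {n_years} too short for lag {coupling.lag}: need n_years > lag + 4"
        )
    rng = np.random.default_rng(seed)
    lag = coupling.lag
    years = np.arange(start_year, start_year + n_years)
    struct_cols = ("ln_N", "diversity_adj", "seg_sum")
    inits = {"ln_N": (np.log(1e5), np.log(5e6)), "diversity_adj": (-3.0, -1.4),
             "seg_sum": (0.05, 0.5)}
    panels: list[CityPanel] = []
    for i in range(n_cities):
        t_ext = n_years + lag  # extra leading steps so lagged values exist at t=0
        drift = {c: rng.normal(0.0, drift_sd) for c in struct_cols}
        data: dict[str, np.ndarray] = {}
        ln_b_ext = np.empty(t_ext)
        if coupling.direction == "bias->structural":
            ln_b_ext[0] = rng.uniform(-1.5, -0.5)
            ln_b_ext[1:] = rng.normal(0.0, rw_sd, t_ext - 1)
            ln_b_ext = np.cumsum(ln_b_ext)
            for c in struct_cols:
                x = np.empty(t_ext)
                x[0] = rng.uniform(*inits[c])
                innov = rng.normal(0.0, rw_sd, t_ext - 1)
                coupled = c in coupling.variables
                for t in range(1, t_ext):
                    fb = coupling.strength * ln_b_ext[t - lag] if (coupled and t >= lag) else 0.0
                    x[t] = x[t - 1] + drift[c] + fb + innov[t - 1]
                data[c] = x[lag:]
            data["ln_b"] = ln_b_ext[lag:]
        else:
            for c in struct_cols:
                steps = rng.normal(drift[c], rw_sd, t_ext - 1)
                x0 = rng.uniform(*inits[c])
                data[c] = np.concatenate([[x0], x0 + np.cumsum(steps)])
            if coupling.direction == "structural->bias":
                a = rng.uniform(-1.5, -0.5)
                lagged = sum(data[c][: t_ext - lag] if lag else data[c] for c in coupling.variables)
                ln_b = a + coupling.strength * lagged + rng.normal(0.0, bias_noise_sd, t_ext - lag)
                data = {c: v[lag:] for c, v in data.items()}
                data["ln_b"] = ln_b[: n_years] if lag == 0 else ln_b
            elif coupling.direction == "none":
                # bias fluctuates around a city level, independent of everything
                a = rng.uniform(-1.5, -0.5)
                ln_b = a + rng.normal(0.0, bias_noise_sd, t_ext)
                data = {c: v[lag:] for c, v in data.items()}
                data["ln_b"] = ln_b[lag:]
            else:
                raise ValueError(f"unknown coupling direction {coupling.direction!r}")
        frame = pd.DataFrame(data, index=pd.Index(years, name="year"))
        panels.append(CityPanel(city_id=f"city{i:04d}", series=frame[list(CityPanel.PANEL_COLUMNS)]))
    return panels


def crossed_cities(
    *,
    compositions: Sequence[float] = (0.55, 0.65, 0.75, 0.85, 0.90),
    share_spreads: Sequence[float] = (0.02, 0.06, 0.10),
    n_scales: int = 10,
    base_total: int = 10_000,
    scale_step: float = 1.8,
) -> list[City]:
    """Deterministic fully-crossed city design for exact-recovery checks.

    Builds two-tract template cities (equal tract sizes, group-1 tract
    shares f1 +/- spread) for every (composition, spread) combination, all
    with the same base population, then replicates each template at
    ``n_scales`` geometrically spaced population scales by multiplying all
    tract counts by an integer factor.  Segregation measures and group
    fractions are scale invariant, so composition and segregation are
    exactly orthogonal to ln N in the resulting sample -- the property the
    two-stage regression needs to recover the forward-model coefficients
    exactly on noise-free data.
    """
    half = base_total // 2
    templates: list[np.ndarray] = []
    for f1 in compositions:
        for e in share_spreads:
            hi = int(round(half * (f1 + e)))
            lo = int(round(half * (f1 - e)))
            counts = np.array([[hi, half - hi], [lo, half - lo]], dtype=np.int64)
            templates.append(counts)
    factors = [max(1, int(round(scale_step**j))) for j in range(n_scales)]
    cities = []
    for j, k in enumerate(factors):
        for t, counts in enumerate(templates):
            cities.append(City(city_id=f"t{t:02d}s{j:02d}", tract_counts=counts * k))
    return cities
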