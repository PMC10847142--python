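"""CSV contracts, covariate recoding, and delineation mapping.

All tables are plain UTF-8 CSV with a header row:

* ``tracts.csv``      -- city_id, tract_id, count_group1, count_group2
* ``cities.csv``      -- city_id, N, N1, N2
* ``bias.csv``        -- city_id, year, b, n_respondents
* ``respondents.csv`` -- city_id, year, d_biep, race_raw, edu14, birth_sex
* ``panel.csv``       -- city_id, year, ln_N, diversity_adj, seg_sum, ln_b

Integer counts round-trip losslessly; reals are serialized at full
precision (repr).  Results are JSON.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import BiasObservation, City, CityPanel

logger = logging.getLogger(__name__)

TRACT_COLUMNS = ["city_id", "tract_id", "count_group1", "count_group2"]
CITY_COLUMNS = ["city_id", "N", "N1", "N2"]
BIAS_COLUMNS = ["city_id", "year", "b", "n_respondents"]
RESPONDENT_COLUMNS = ["city_id", "year", "d_biep", "race_raw", "edu14", "birth_sex"]
PANEL_COLUMNS = ["city_id", "year", "ln_N", "diversity_adj", "seg_sum", "ln_b"]

EDUCATION_LEVELS = ("HS-or-below", "some-college-or-grad", "advanced")
#: edu_14 cut points: codes <= first bound -> HS-or-below, <= second bound ->
#: some-college-or-grad, the rest -> advanced.  Configurable per call.
DEFAULT_EDU_CUTS = (6, 11)

RACE_LEVELS = ("White", "Black", "Multiracial", "other-base")
#: Raw self-reported race labels mapped onto the three modelled categories;
#: anything absent from the map (including unknown/empty) is the base level.
DEFAULT_RACE_MAP = {
    "White": "White",
    "Black": "Black",
    "Black or African American": "Black",
    "Multiracial": "Multiracial",
    "Multi-racial": "Multiracial",
}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


@dataclass(frozen=True)
class DelineationMap:
    """Mapping from tract id to city id (tract -> CBSA delineation)."""

    mapping: Mapping[str, str]

    def city_for(self, tract_id: str) -> str | None:
        return self.mapping.get(tract_id)


def read_delineation(path) -> DelineationMap:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["tract_id", "city_id"], path)
    if df["tract_id"].duplicated().any():
        dupes = df.loc[df["tract_id"].duplicated(), "tract_id"].tolist()
        raise ValueError(f"{path}: tract(s) {dupes} map to more than one city")
    return DelineationMap(mapping=dict(zip(df["tract_id"], df["city_id"])))


def write_tracts(cities: Sequence[City], path) -> None:
    rows = []
    for city in cities:
        for m in range(city.n_tracts):
            rows.append((city.city_id, f"{city.city_id}-t{m:05d}",
                         int(city.tract_counts[m, 0]), int(city.tract_counts[m, 1])))
    pd.DataFrame(rows, columns=TRACT_COLUMNS).to_csv(path, index=False)


def read_tracts(path, *, delineation: DelineationMap | None = None) -> list[City]:
    """Read tract counts into City objects, optionally joining a delineation map.

    With a delineation map the city assignment comes from the map; tracts
    the map does not know are excluded with a warning.  Rows with negative
    counts or a nonpositive tract total raise row-numbered errors.
    """
    df = pd.read_csv(path)
    _require_columns(df, [c for c in TRACT_COLUMNS if delineation is None or c != "city_id"], path)
    counts = df[["count_group1", "count_group2"]].to_numpy()
    bad = np.nonzero((counts < 0).any(axis=1))[0]
    if bad.size:
        raise ValueError(f"{path}: negative count in data row(s) {(bad + 2).tolist()}")
    empty = np.nonzero(counts.sum(axis=1) <= 0)[0]
    if empty.size:
        raise ValueError(f"{path}: nonpositive tract total in data row(s) {(empty + 2).tolist()}")
    if delineation is not None:
        mapped = df["tract_id"].astype(str).map(delineation.mapping)
        unmapped = df.loc[mapped.isna(), "tract_id"]
        for t in unmapped:
            logger.warning("tract %s has no city in the delineation map; excluded", t)
        df = df.assign(city_id=mapped).dropna(subset=["city_id"])
    cities = []
    for city_id, grp in df.groupby("city_id", sort=True):
        cities.append(City(city_id=str(city_id),
                           tract_counts=grp[["count_group1", "count_group2"]].to_numpy()))
    return cities


def write_cities(cities: Sequence[City], path) -> None:
    rows = [(c.city_id, c.total, int(c.group_totals[0]), int(c.group_totals[1])) for c in cities]
    pd.DataFrame(rows, columns=CITY_COLUMNS).to_csv(path, index=False)


def write_bias(observations: Sequence[BiasObservation], path) -> None:
    rows = [(o.city_id, o.year, repr(o.b), o.n_respondents) for o in observations]
    pd.DataFrame(rows, columns=BIAS_COLUMNS).to_csv(path, index=False)


def read_bias(path, *, min_responses: int = 500) -> list[BiasObservation]:
    """Read city-year mean bias observations.

    Cities are retained when n_respondents > ``min_responses`` (pass 0 to
    keep everything); the same cutoff convention as the scaling fit.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, BIAS_COLUMNS, path)
    out = []
    for _, row in df.iterrows():
        if int(row["n_respondents"]) <= min_responses:
            continue
        out.append(BiasObservation(city_id=str(row["city_id"]), year=int(row["year"]),
                                   b=float(row["b"]), n_respondents=int(row["n_respondents"])))
    return out


def write_respondents(responses: pd.DataFrame, path) -> None:
    responses[RESPONDENT_COLUMNS].to_csv(path, index=False)


def read_respondents(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, RESPONDENT_COLUMNS, path)
    return df


def write_panels(panels: Sequence[CityPanel], path) -> None:
    frames = []
    for p in panels:
        f = p.series.reset_index()
        f.insert(0, "city_id", p.city_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True)[PANEL_COLUMNS].to_csv(path, index=False)


def read_panels(path) -> list[CityPanel]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PANEL_COLUMNS, path)
    panels = []
    for city_id, grp in df.groupby("city_id", sort=True):
        series = grp.set_index("year")[["ln_N", "diversity_adj", "seg_sum", "ln_b"]].sort_index()
        panels.append(CityPanel(city_id=str(city_id), series=series))
    return panels


def recode_education(edu14, cuts: tuple[int, int] = DEFAULT_EDU_CUTS):
    """Collapse the 14-point educational attainment code to three levels.

    Codes 1..cuts[0] -> 'HS-or-below', cuts[0]+1..cuts[1] ->
    'some-college-or-grad', the rest up to 14 -> 'advanced'.  Missing stays
    missing; out-of-range codes raise.
    """
    if edu14 is None or (isinstance(edu14, float) and np.isnan(edu14)):
        return None
    code = int(edu14)
    if not 1 <= code <= 14:
        raise ValueError(f"edu_14 code {code} out of range 1..14")
    if code <= cuts[0]:
        return EDUCATION_LEVELS[0]
    if code <= cuts[1]:
        return EDUCATION_LEVELS[1]
    return EDUCATION_LEVELS[2]


def recode_race(raw, code_map: Mapping[str, str] | None = None) -> str:
    """Collapse raw self-reported race to White / Black / Multiracial / other-base.

    Unknown, empty, and unmapped values all become the base category.  A
    custom ``code_map`` (raw label -> level) supports numeric code lists.
    """
    table = DEFAULT_RACE_MAP if code_map is None else code_map
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "other-base"
    return table.get(str(raw).strip(), "other-base")
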