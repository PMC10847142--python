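#!/usr/bin/env python
"""Generate the synthetic study world: 150 two-group cities with tract-level
counts spanning the CBSA population range, plus noisy mean-bias observations
and respondent-level D-scores for the 2020 cross-section.

Writes tracts.csv, cities.csv, bias.csv, respondents.csv under results/synthetic/.
"""

import argparse
from pathlib import Path

from urbanbias import io
from urbanbias.datatypes import ModelParameters
from urbanbias.synthetic import generate_bias, generate_cities, generate_respondents


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-cities", type=int, default=150)
    parser.add_argument("--out-dir", type=Path, default=Path("results/synthetic"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    params = ModelParameters()
    cities = generate_cities(params, args.n_cities, seed=args.seed)
    observations = generate_bias(cities, params, seed=args.seed + 1)
    respondents = generate_respondents(
        [type(o)(o.city_id, o.year, o.b, 60) for o in observations[:100]],
        params, seed=args.seed + 2,
    )
    io.write_tracts(cities, args.out_dir / "tracts.csv")
    io.write_cities(cities, args.out_dir / "cities.csv")
    io.write_bias(observations, args.out_dir / "bias.csv")
    io.write_respondents(respondents, args.out_dir / "respondents.csv")

    pops = [c.total for c in cities]
    print(f"wrote {len(cities)} cities to {args.out_dir}")
    print(f"population range: {min(pops):,} .. {max(pops):,}")
    print(f"bias observations: {len(observations)} (mean b = "
          f"{sum(o.b for o in observations) / len(observations):.3f})")
    print(f"respondents: {len(respondents)} across {respondents['city_id'].nunique()} cities")


if __name__ == "__main__":
    main()
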