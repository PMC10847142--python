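#!/usr/bin/env python
"""Temporal precedence on multi-year panels: generate 43-city panels where
structural change drives bias at a one-year lag, test both directions at lags
1 and 2 for each structural variable, and summarize percentages with
bootstrap standard errors.

Writes results/panel.csv and results/precedence.csv.
"""

import argparse
from pathlib import Path

from urbanbias import io
from urbanbias.precedence import STRUCTURAL_VARIABLES, summarize, summary_table
from urbanbias.synthetic import Coupling, generate_panel


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-cities", type=int, default=43)
    parser.add_argument("--n-years", type=int, default=10)
    parser.add_argument("--strength", type=float, default=2.0)
    parser.add_argument("--n-boot", type=int, default=1000)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    coupling = Coupling("structural->bias", lag=1, strength=args.strength)
    panels = generate_panel(args.n_cities, args.n_years, coupling,
                            seed=args.seed, bias_noise_sd=0.02)
    io.write_panels(panels, args.out_dir / "panel.csv")

    summaries = []
    for var in STRUCTURAL_VARIABLES:
        summaries.extend(
            summarize(panels, var, lags=(1, 2), n_boot=args.n_boot, seed=args.seed + 1)
        )
    table = summary_table(summaries)
    table.to_csv(args.out_dir / "precedence.csv")

    print(f"precedence over {args.n_cities} cities x {args.n_years} years "
          f"-> {args.out_dir / 'precedence.csv'}")
    print(table)
    fwd = [s for s in summaries if s.direction[1] == "ln_b" and s.lag == 1]
    rev = [s for s in summaries if s.direction[0] == "ln_b" and s.lag == 1]
    print(f"lag-1 structural->bias mean: {sum(s.pct_significant for s in fwd) / 3:.1f}% | "
          f"reverse: {sum(s.pct_significant for s in rev) / 3:.1f}%")


if __name__ == "__main__":
    main()
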