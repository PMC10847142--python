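#!/usr/bin/env python
"""Split-half noise ceiling of city-level mean bias from the respondent table,
and the noise-corrected total-model R^2.

Reads results/synthetic/respondents.csv and results/fit.json;
writes results/ceiling.json.
"""

import argparse
import json
from pathlib import Path

from urbanbias import io
from urbanbias.ceiling import corrected_r2, estimate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--respondents", type=Path,
                        default=Path("results/synthetic/respondents.csv"))
    parser.add_argument("--fit", type=Path, default=Path("results/fit.json"))
    parser.add_argument("--n-splits", type=int, default=500)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/ceiling.json"))
    args = parser.parse_args()

    responses = io.read_respondents(args.respondents)
    nc = estimate(responses, n_splits=args.n_splits, seed=args.seed)
    out = {"lower": nc.lower, "upper": nc.upper, "n_splits": nc.n_splits}
    if args.fit.exists():
        r2 = json.loads(args.fit.read_text())["mean_deviance"]["r2_total_model"]
        out["r2_total_model"] = r2
        out["noise_corrected_r2"] = corrected_r2(r2, nc)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")

    print(f"noise ceiling over {responses['city_id'].nunique()} cities -> {args.out}")
    print(f"lower = {nc.lower:.3f}, upper = {nc.upper:.3f} ({nc.n_splits} splits)")
    if "noise_corrected_r2" in out:
        print(f"model R^2 = {out['r2_total_model']:.3f} -> "
              f"noise-corrected R^2 = {out['noise_corrected_r2']:.3f}")


if __name__ == "__main__":
    main()
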