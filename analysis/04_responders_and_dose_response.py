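#!/usr/bin/env python
"""Responder proportions and the bolus size/rate dose-response models.

Classifies each matched episode as responder (>10% increase of the
variable above its 30-min baseline, using the maximum 5-min bin) for CO,
SV, MAP and VIS; compares the proportions with Pearson's chi-squared
test; and fits the per-outcome linear models of the mean post-bolus
change on bolus size (per 100 ml) and infusion rate with the baseline
covariate set.  Writes both tables under results/.
"""

import pathlib
import sys

import pandas as pd

from fbt import analyze

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> int:
    scratch = ROOT / "scratch" / "analysis"
    binned = pd.read_csv(scratch / "binned.csv")
    baselines = pd.read_csv(scratch / "baselines.csv")
    eps = pd.read_csv(scratch / "episodes.csv",
                      parse_dates=["start_ts", "end_ts",
                                   "window_start_ts", "window_end_ts"])

    rows = [
        analyze.classify_responders(binned, var).to_row()
        for var in ("co", "sv", "map", "vis")
    ]
    resp = pd.DataFrame(rows)
    print("responder proportions (>10% above baseline, max 5-min bin):")
    print(resp.round(4).to_string(index=False))

    matched = eps[eps["episode_id"].isin(binned["episode_id"])]
    models = analyze.fit_size_rate_models(binned, baselines, matched)
    tables = []
    for m in models:
        t = m.table.assign(outcome=m.outcome, n=m.n)
        tables.append(t)
        size = m.coef("size_100ml")
        rate = m.coef("rate_ml_min")
        print(f"{m.outcome}: per-100-ml effect {size[0]:+.3f} "
              f"({size[1]:.3f} to {size[2]:.3f}); "
              f"per-ml/min rate effect {rate[0]:+.4f} "
              f"({rate[1]:.4f} to {rate[2]:.4f}); n={m.n}")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    resp.to_csv(results / "responders.csv", index=False)
    pd.concat(tables, ignore_index=True).to_csv(
        results / "size_rate_models.csv", index=False
    )
    print("wrote results/responders.csv, results/size_rate_models.csv")
    return 0


if __name__ == "__main__":
    sys.exit(main())
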