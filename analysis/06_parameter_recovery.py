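#!/usr/bin/env python
"""Parameter-recovery simulation for the published severity slopes.

For each generating slope / case-count pair (per organ system plus the
no-malformation indicator), repeatedly simulates a cohort of 1,062 subjects
and refits the IRLS GLM, reporting the mean recovered slope and its
Monte-Carlo standard error.  Well-populated outcomes recover their slope
almost exactly; rare outcomes (≈60 events) show the expected small upward
maximum-likelihood bias of a few percent.

Scaled down to 50 replicates by default to stay desk-fast; pass
--replicates 200 for the full run.
"""

import argparse

import pandas as pd

from vertpattern.simulate import DEFAULT_SYSTEM_PARAMS, slope_recovery


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replicates", type=int, default=50)
    args = ap.parse_args()

    outcomes = dict(DEFAULT_SYSTEM_PARAMS)
    outcomes["No-Mal"] = (-0.11, 357)

    rows = []
    for i, (name, (slope, cases)) in enumerate(outcomes.items()):
        res = slope_recovery(slope, cases, n_replicates=args.replicates,
                             seed=(args.seed * 13 + i) % (2**31 - 1))
        rows.append({"outcome": name, "generating": slope, "cases": cases,
                     "mean_estimate": round(res.mean_slope, 4),
                     "mc_se": round(res.mc_se, 4),
                     "bias": round(res.mean_slope - slope, 4)})
    table = pd.DataFrame(rows)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
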