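#!/usr/bin/env python
"""Code the cohort's autopsy findings into primary organ-system flags.

Reads results/cohort/findings.csv, writes results/coded.csv and prints the
per-system affected counts plus germ-layer / process marginals.
"""

import argparse
from pathlib import Path

from vertpattern import io as vio
from vertpattern.malformations import GERM_LAYERS, ORGAN_SYSTEMS, PROCESSES
from vertpattern.pipeline import code_findings_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--findings", type=Path, default=Path("results/cohort/findings.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/coded.csv"))
    args = ap.parse_args()

    per_subject = vio.read_findings(args.findings)
    table = code_findings_table(per_subject)
    vio.write_table(table, args.out, "coded")

    n = len(table)
    print(f"coded {n} subjects -> {args.out}")
    for sys in ORGAN_SYSTEMS:
        affected = (table[f"status_{sys}"] == "affected").sum()
        na = (table[f"status_{sys}"] == "non_available").sum()
        print(f"  {sys:<4} affected {affected:>4}  non-available {na:>4}")
    print("germ layers:", {l: int(table[f'layer_{l}'].sum()) for l in GERM_LAYERS})
    print("processes:  ", {p: int(table[f'process_{p}'].sum()) for p in PROCESSES})
    print("no malformations:", int((table["n_affected"] == 0).sum()))


if __name__ == "__main__":
    main()
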