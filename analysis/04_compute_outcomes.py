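#!/usr/bin/env python
"""Derive BP_P and BP_ND from regional V_T with the cerebellar reference.

Reads results/kinetics.csv, writes results/outcomes.csv, and prints the
group-mean outcome per region.
"""

import argparse
from pathlib import Path

import pandas as pd

from petrt.outcomes import outcomes_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--kinetics", type=Path, default=Path("results/kinetics.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/outcomes.csv"))
    args = ap.parse_args()

    kin = pd.read_csv(args.kinetics)
    out = outcomes_table(kin[["subject", "session", "region", "VT"]])
    args.out.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out, index=False)

    means = out.groupby("region")[["VT", "BPP", "BPND"]].mean().round(2)
    print(means.to_string())


if __name__ == "__main__":
    main()
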