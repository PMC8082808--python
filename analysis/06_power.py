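#!/usr/bin/env python
"""Design power: two-sided Pearson-correlation test at the cohort size
(n=21) for a large effect (r=0.5), at the Bonferroni-adjusted level
0.1/50 = 0.002, plus the sample sizes needed for conventional power.
Writes results/power/power.tsv."""

from pathlib import Path

import pandas as pd

from microperm.power import PowerQuery, bonferroni_threshold, correlation_power

OUT = Path(__file__).resolve().parent.parent / "results" / "power"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    alpha = bonferroni_threshold(0.1, 50)
    print(f"Bonferroni-adjusted alpha for 50 genera at family level 0.1: {alpha}")

    rows = []
    for n in (10, 21, 50, 100, 200):
        p = correlation_power(PowerQuery(n=n, r=0.5, alpha=alpha, sides=2))
        rows.append({"n": n, "r": 0.5, "alpha": alpha, "power": p})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "power.tsv", sep="\t", index=False)
    design = table.loc[table["n"] == 21, "power"].iloc[0]
    print(f"power at the cohort size n=21: {design:.3f} (~{100 * design:.0f}%)")
    print("power by n:")
    print(table.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
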